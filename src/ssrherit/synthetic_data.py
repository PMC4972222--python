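"""Ground-truth simulation of genotypes, pedigrees, traits and loggers.

The generator emulates the study system the package targets: a clonal
alpine dwarf shrub sampled as ~1000 patches across 12 sites in a
3 (transect) x 2 (elevation) x 2 (microhabitat) layout, genotyped at 7
highly polymorphic SSR loci (~23 alleles each, a skewed Dirichlet
frequency spectrum), with a fraction of patches being exact clonal
copies of the same genet.  Traits follow the animal-model forward
equation ``y = X b + a + e`` with breeding values drawn from
``N(0, Va * A)`` for a pedigree-derived additive relationship matrix
``A``, so every pipeline stage can be checked against known truth.

All generators take explicit seeds and record them in the returned
:class:`SimulationTruth`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ssrherit.genotype_io import AlleleFrequencyTable, GenotypeTable
from ssrherit.phenotypes import TemperatureSeries

TRANSECTS = ("J", "S", "W")
ELEVATIONS = ("low", "high")
MICROHABITATS = ("ridge", "snowbed")


@dataclass
class SimulationTruth:
    """Everything the generator knows that an analysis must recover."""

    pedigree: pd.DataFrame | None = None
    A: np.ndarray | None = None
    genet_ids: list[str] = field(default_factory=list)
    founder_freqs: AlleleFrequencyTable | None = None
    clone_map: dict[str, str] = field(default_factory=dict)
    breeding_values: pd.DataFrame | None = None
    va: dict[str, float] = field(default_factory=dict)
    ve: dict[str, float] = field(default_factory=dict)
    h2: dict[str, float] = field(default_factory=dict)
    fixed_effects: dict = field(default_factory=dict)
    genetic_corr: np.ndarray | None = None
    snowmelt_days: dict[str, int] = field(default_factory=dict)
    seeds: dict[str, int] = field(default_factory=dict)


def simulate_founder_frequencies(
    n_loci: int = 7,
    alleles_per_locus: int = 23,
    alpha: float = 0.3,
    seed: int = 0,
) -> AlleleFrequencyTable:
    """Skewed SSR allele-frequency spectra, Dirichlet(alpha) per locus.

    Allele "sizes" are base-pair labels ``100 + 2k`` per locus.
    """
    rng = np.random.default_rng(seed)
    freqs = {}
    for j in range(n_loci):
        p = rng.dirichlet(np.full(alleles_per_locus, alpha))
        p = np.maximum(p, 1e-6)
        p = p / p.sum()
        freqs[f"L{j + 1}"] = {
            100 + 2 * k: float(p[k]) for k in range(alleles_per_locus)
        }
    return AlleleFrequencyTable(freqs)


def _sample_hwe_calls(
    f: AlleleFrequencyTable, n: int, rng: np.random.Generator
) -> np.ndarray:
    loci = f.locus_names
    calls = np.zeros((n, len(loci), 2), dtype=np.int64)
    for j, name in enumerate(loci):
        alleles, p = f.arrays(name)
        calls[:, j, 0] = rng.choice(alleles, size=n, p=p)
        calls[:, j, 1] = rng.choice(alleles, size=n, p=p)
    return np.sort(calls, axis=2)


def pedigree_relationship(pedigree: pd.DataFrame) -> np.ndarray:
    """Additive relationship matrix A from a pedigree (tabular method).

    ``pedigree`` has columns ``id``, ``sire``, ``dam`` (NaN/None for
    founders), parents listed before offspring.
    """
    ids = list(pedigree["id"])
    index = {x: i for i, x in enumerate(ids)}
    n = len(ids)
    a = np.zeros((n, n))
    sires = pedigree["sire"].tolist()
    dams = pedigree["dam"].tolist()
    for i in range(n):
        s = index.get(sires[i]) if pd.notna(sires[i]) else None
        d = index.get(dams[i]) if pd.notna(dams[i]) else None
        for j in range(i):
            val = 0.0
            if s is not None:
                val += 0.5 * a[j, s]
            if d is not None:
                val += 0.5 * a[j, d]
            a[i, j] = a[j, i] = val
        a[i, i] = 1.0 + (0.5 * a[s, d] if s is not None and d is not None else 0.0)
    return a


def simulate_genotypes(
    n_founders: int = 500,
    n_descendant_generations: int = 1,
    n_loci: int = 7,
    alleles_per_locus: int = 23,
    clone_rate: float = 0.1,
    seed: int = 0,
    n_per_generation: int | None = None,
    family_size: int = 4,
    freq_alpha: float = 0.3,
) -> tuple[GenotypeTable, SimulationTruth]:
    """Simulate SSR genotypes for a pedigree plus exact clonal copies.

    Founder gametes are drawn from per-locus Dirichlet spectra;
    descendants are produced in full-sib families of ``family_size``
    (each family a random parent pair of the previous generation, as in
    seed families of an outcrossing plant), inheriting one allele per
    locus from each parent.  ``clone_rate`` of the genets are duplicated
    as error-free genotype copies (extra patches).  The pedigree-based
    additive relationship matrix ``A`` over genets, the clone map and
    the generating frequencies are recorded as truth.
    """
    rng = np.random.default_rng(seed)
    f = simulate_founder_frequencies(
        n_loci, alleles_per_locus, freq_alpha, seed=int(rng.integers(2**31))
    )
    loci = f.locus_names
    calls = _sample_hwe_calls(f, n_founders, rng)
    ids = [f"G{i + 1:05d}" for i in range(n_founders)]
    sires: list[object] = [None] * n_founders
    dams: list[object] = [None] * n_founders
    gen_of = [0] * n_founders
    n_gen = n_per_generation or n_founders
    prev_start = 0
    for g in range(1, n_descendant_generations + 1):
        prev = list(range(prev_start, len(ids)))
        prev_start = len(ids)
        new_calls = np.zeros((n_gen, len(loci), 2), dtype=np.int64)
        k = 0
        while k < n_gen:
            s, d = rng.choice(prev, size=2, replace=False)
            for _ in range(min(family_size, n_gen - k)):
                for j in range(len(loci)):
                    new_calls[k, j, 0] = calls[s, j, rng.integers(2)]
                    new_calls[k, j, 1] = calls[d, j, rng.integers(2)]
                ids.append(f"G{len(ids) + 1:05d}")
                sires.append(ids[s])
                dams.append(ids[d])
                gen_of.append(g)
                k += 1
        calls = np.vstack([calls, np.sort(new_calls, axis=2)])
    pedigree = pd.DataFrame(
        {"id": ids, "sire": sires, "dam": dams, "generation": gen_of}
    )
    a = pedigree_relationship(pedigree)

    n_genets = len(ids)
    n_clones = int(round(clone_rate * n_genets))
    clone_sources = rng.choice(n_genets, size=n_clones, replace=False)
    patch_ids = list(ids)
    patch_calls = [calls]
    clone_map = {pid: pid for pid in ids}
    for c, src in enumerate(sorted(clone_sources)):
        pid = f"{ids[src]}_c1"
        patch_ids.append(pid)
        clone_map[pid] = ids[src]
    if n_clones:
        patch_calls.append(calls[sorted(clone_sources)])
    table = GenotypeTable(patch_ids, loci, np.vstack(patch_calls))
    truth = SimulationTruth(
        pedigree=pedigree,
        A=a,
        genet_ids=list(ids),
        founder_freqs=f,
        clone_map=clone_map,
        seeds={"genotypes": seed},
    )
    return table, truth


def simulate_pairs(
    f: AlleleFrequencyTable,
    n_pairs: int,
    relationship: str = "unrelated",
    seed: int = 0,
) -> GenotypeTable:
    """Independent dyads with known relatedness, from known frequencies.

    ``relationship``: ``"unrelated"`` (r = 0) or ``"parent_offspring"``
    (r = 0.5; the offspring receives one allele of the parent and one
    population allele per locus).  Members of pair ``i`` get ids
    ``P{i}a`` / ``P{i}b``.
    """
    rng = np.random.default_rng(seed)
    loci = f.locus_names
    first = _sample_hwe_calls(f, n_pairs, rng)
    if relationship == "unrelated":
        second = _sample_hwe_calls(f, n_pairs, rng)
    elif relationship == "parent_offspring":
        second = np.zeros_like(first)
        for j, name in enumerate(loci):
            alleles, p = f.arrays(name)
            transmitted = first[np.arange(n_pairs), j, rng.integers(2, size=n_pairs)]
            second[:, j, 0] = transmitted
            second[:, j, 1] = rng.choice(alleles, size=n_pairs, p=p)
        second = np.sort(second, axis=2)
    else:
        raise ValueError(f"unknown relationship {relationship!r}")
    calls = np.empty((2 * n_pairs, len(loci), 2), dtype=np.int64)
    calls[0::2] = first
    calls[1::2] = second
    ids = [x for i in range(n_pairs) for x in (f"P{i}a", f"P{i}b")]
    return GenotypeTable(ids, loci, calls)


def assign_sites(
    ids: list[str], seed: int = 0
) -> pd.DataFrame:
    """Random assignment of individuals to the 12-site factorial layout."""
    rng = np.random.default_rng(seed)
    sites = [
        (t, e, m, f"{t}-{e}-{m}")
        for t in TRANSECTS
        for e in ELEVATIONS
        for m in MICROHABITATS
    ]
    picks = rng.integers(len(sites), size=len(ids))
    rows = [
        {
            "id": ids[i],
            "transect": sites[k][0],
            "elevation": sites[k][1],
            "microhabitat": sites[k][2],
            "site": sites[k][3],
        }
        for i, k in enumerate(picks)
    ]
    return pd.DataFrame(rows).set_index("id")


def _psd_factor(a: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eigh(0.5 * (a + a.T))
    if w.min() < -1e-8 * max(w.max(), 1.0):
        raise ValueError("relationship matrix A is not positive semi-definite")
    return v * np.sqrt(np.clip(w, 0.0, None))


def simulate_traits(
    A: np.ndarray,
    h2: float | list[float],
    total_variance: float | list[float] = 1.0,
    factors: pd.DataFrame | None = None,
    effects: dict[str, dict[str, dict[str, float]]] | None = None,
    trait_names: list[str] | None = None,
    genetic_corr: np.ndarray | None = None,
    intercepts: list[float] | None = None,
    ids: list[str] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Simulate one or more traits under the animal-model forward equation.

    Breeding values are drawn with covariance ``Va * A`` (via a PSD
    eigenfactor of ``A``), residuals i.i.d. ``N(0, Ve)``, and fixed
    effects added per factor level.  For several traits a genetic
    correlation matrix may couple the breeding values; residuals stay
    independent across traits.

    ``effects`` maps trait -> factor column -> level -> additive shift,
    e.g. ``{"y1": {"microhabitat": {"snowbed": 2.0}}}``.
    """
    a = np.asarray(A, dtype=float)
    n = a.shape[0]
    h2_vec = np.atleast_1d(np.asarray(h2, dtype=float))
    k = len(h2_vec)
    if np.any((h2_vec < 0) | (h2_vec > 1)):
        raise ValueError("h2 must lie in [0, 1]")
    tot = np.broadcast_to(np.atleast_1d(np.asarray(total_variance, float)), (k,))
    names = trait_names or [f"y{i + 1}" for i in range(k)]
    ids = list(ids) if ids is not None else [f"G{i + 1:05d}" for i in range(n)]
    if factors is None:
        factors = assign_sites(ids, seed=seed + 1)
    factors = factors.loc[ids]
    rng = np.random.default_rng(seed)

    va = h2_vec * tot
    ve = (1.0 - h2_vec) * tot
    la = _psd_factor(a)
    z = rng.standard_normal((n, k))
    if genetic_corr is not None:
        gc = np.asarray(genetic_corr, dtype=float)
        lg = np.linalg.cholesky(gc)
        z = z @ lg.T
    bv = (la @ z) * np.sqrt(va)[None, :]
    resid = rng.standard_normal((n, k)) * np.sqrt(ve)[None, :]

    out = factors.copy()
    effects = effects or {}
    intercepts = intercepts or [0.0] * k
    for t, name in enumerate(names):
        y = intercepts[t] + bv[:, t] + resid[:, t]
        for factor_col, level_map in effects.get(name, {}).items():
            shift = factors[factor_col].map(lambda lv: level_map.get(lv, 0.0))
            y = y + shift.to_numpy(dtype=float)
        out[name] = y
    truth = SimulationTruth(
        A=a,
        genet_ids=ids,
        breeding_values=pd.DataFrame(bv, index=ids, columns=names),
        va={nm: float(v) for nm, v in zip(names, va)},
        ve={nm: float(v) for nm, v in zip(names, ve)},
        h2={nm: float(v) for nm, v in zip(names, h2_vec)},
        fixed_effects=effects,
        genetic_corr=genetic_corr,
        seeds={"traits": seed},
    )
    return out, truth


def simulate_temperature(
    site: str = "site1",
    snowmelt_day: int = 160,
    winter_mean: float = 0.0,
    summer_peak: float = 12.0,
    noise_sd: float = 0.3,
    start_day: int = 60,
    end_day: int = 280,
    year: int = 2012,
    seed: int = 0,
) -> TemperatureSeries:
    """Synthetic 2-h soil-temperature series with a planted snowmelt day.

    Before ``snowmelt_day`` the soil sits at ``winter_mean`` (snow
    insulation); from the snowmelt day onwards temperature jumps to a
    seasonal half-sine reaching ``summer_peak``, with a small diurnal
    cycle and Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    hours = np.arange((end_day - start_day + 1) * 12) * 2.0
    days = start_day + (hours // 24).astype(int)
    base = np.where(days < snowmelt_day, winter_mean, 0.0)
    progress = np.clip(
        (days - snowmelt_day) / max(end_day - snowmelt_day, 1), 0.0, 1.0
    )
    seasonal = 3.0 + (summer_peak - 3.0) * np.sin(np.pi * np.minimum(progress, 0.999))
    base = base + np.where(days >= snowmelt_day, seasonal, 0.0)
    diurnal = np.where(
        days >= snowmelt_day, 1.5 * np.sin(2.0 * np.pi * (hours % 24) / 24.0), 0.0
    )
    temp = base + diurnal + (rng.standard_normal(len(hours)) * noise_sd if noise_sd else 0.0)
    t0 = pd.Timestamp(year=year, month=1, day=1) + pd.to_timedelta(
        start_day - 1, unit="D"
    )
    timestamps = t0 + pd.to_timedelta(hours, unit="h")
    return TemperatureSeries(site, pd.DatetimeIndex(timestamps), temp)


def phenology_records_from_traits(
    phenotypes: pd.DataFrame,
    snowmelt_days: dict[str, int],
    seed: int = 0,
) -> pd.DataFrame:
    """Raw field-record table consistent with a simulated trait table.

    Produces one row per patch with phenophase days, stem counts and
    leaf dimensions whose derived traits are monotone transforms of the
    simulated (dimensionless) traits — field-scale plumbing for the
    record-to-trait derivation path, not an inverse of it.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for patch, rec in phenotypes.iterrows():
        melt = snowmelt_days[rec["site"]]
        interval = max(1, round(20 + 7 * rec["snowmelt_to_leaf_expansion"]))
        flower_lag = max(1, round(7 + 3 * rec["gdd_to_flowering"]))
        stems_2011 = int(5 + rng.poisson(20))
        ratio = max(0.05, 1.0 + 0.2 * rec["change_in_stem_number"])
        stems_2012 = max(1, round(stems_2011 * ratio))
        prop = 1.0 / (1.0 + np.exp(-(0.25 * rec["proportion_flowering_stems"] - 1.0)))
        area = max(5.0, 60.0 + 15.0 * rec["leaf_size"])
        width = float(np.sqrt(4.0 * area / (2.0 * np.pi)))
        rows.append(
            {
                "patch": patch,
                "site": rec["site"],
                "microhabitat": rec["microhabitat"],
                "elevation": rec["elevation"],
                "transect": rec["transect"],
                "leaf_expansion_day": melt + interval,
                "flowering_day": melt + interval + flower_lag,
                "stems_2011": stems_2011,
                "stems_2012": stems_2012,
                "flowering_stems_2012": int(round(stems_2012 * prop)),
                "leaf_length_mm": 2.0 * width,
                "leaf_width_mm": width,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# study-like preset
# ---------------------------------------------------------------------------

STUDY_LIKE_H2 = {
    "leaf_size": 0.06,
    "change_in_stem_number": 0.07,
    "proportion_flowering_stems": 0.03,
    "snowmelt_to_leaf_expansion": 0.18,
    "gdd_to_leaf_expansion": 0.14,
    "gdd_to_flowering": 0.18,
}


def study_like_dataset(
    seed: int = 0,
    n_founders: int = 350,
    n_descendant_generations: int = 1,
    clone_rate: float = 0.13,
    h2: dict[str, float] | None = None,
) -> dict:
    """A full synthetic study: genotypes + factors + 6 traits + loggers.

    Returns a dict with ``genotypes`` (patches incl. clonal copies),
    ``phenotypes`` (per-patch trait table with factors), ``temperature``
    (site -> :class:`TemperatureSeries`), and ``truth``.  Trait
    generation happens at the patch level: clonal copies share their
    genet's breeding value but draw independent residuals.
    """
    rng = np.random.default_rng(seed)
    h2 = dict(h2 or STUDY_LIKE_H2)
    names = list(h2)
    genotypes, truth = simulate_genotypes(
        n_founders=n_founders,
        n_descendant_generations=n_descendant_generations,
        clone_rate=clone_rate,
        seed=int(rng.integers(2**31)),
    )
    # expand the genet-level A to patch level (clones duplicate rows)
    genet_index = {g: i for i, g in enumerate(truth.genet_ids)}
    patch_ids = list(genotypes.ids)
    rows = [genet_index[truth.clone_map[p]] for p in patch_ids]
    a_patch = truth.A[np.ix_(rows, rows)]
    factors = assign_sites(patch_ids, seed=int(rng.integers(2**31)))
    phenology_effect = {"microhabitat": {"snowbed": 0.5}}
    effects = {nm: phenology_effect for nm in names if nm.startswith(("snowmelt", "gdd"))}
    phenotypes, trait_truth = simulate_traits(
        a_patch,
        [h2[nm] for nm in names],
        total_variance=1.0,
        factors=factors,
        effects=effects,
        trait_names=names,
        ids=patch_ids,
        seed=int(rng.integers(2**31)),
    )
    melt_days = {}
    temperature = {}
    for site in sorted(factors["site"].unique()):
        melt = 140 if site.endswith("ridge") else 175
        melt += int(rng.integers(-5, 6))
        melt_days[site] = melt
        temperature[site] = simulate_temperature(
            site=site, snowmelt_day=melt, seed=int(rng.integers(2**31))
        )
    truth.va.update(trait_truth.va)
    truth.ve.update(trait_truth.ve)
    truth.h2.update(trait_truth.h2)
    truth.breeding_values = trait_truth.breeding_values
    truth.snowmelt_days = melt_days
    truth.seeds["preset"] = seed
    return {
        "genotypes": genotypes,
        "phenotypes": phenotypes,
        "temperature": temperature,
        "factors": factors,
        "truth": truth,
    }
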