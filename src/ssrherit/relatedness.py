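"""Pairwise relatedness from codominant markers, and matrix conditioning.

Four method-of-moments estimators convert shared alleles plus population
allele frequencies into pairwise relatedness coefficients ``r`` (expected
0.5 for parent-offspring, 0 for unrelated pairs):

* ``qg`` — Queller & Goodnight's regression estimator, combined across
  loci as a ratio of summed numerators and denominators, and symmetrized
  by averaging the two reference-individual directions.
* ``li`` — Li's shared-allele similarity rescaled by its unrelated-pair
  expectation ``S0 = 2*a2 - a3`` (``a_k = sum_i p_i^k``), ratio of sums
  across loci.
* ``lr`` — Lynch & Ritland's regression estimator with the published
  inverse-variance locus weights (per-locus weight
  ``w = den / (2 p_a p_b)`` for reference genotype ``(a, b)``),
  symmetrized across reference directions.
* ``wang`` — Wang's genotype-class moment model.  Each locus sorts a
  dyad into one of four observable similarity classes (identical /
  one-homozygote sharing / heterozygotes sharing one allele / no
  sharing) whose probabilities are linear in the two-gene and four-gene
  identity-by-descent coefficients (phi, Delta); the package solves the
  stacked per-locus moment system by least squares and reports
  ``r = phi/2 + Delta``.  The class-probability coefficients are the
  standard ``b..g`` polynomial functions of allele frequencies.

Before use in an animal model the matrix diagonal is set to one (an
individual's relatedness with itself) and the matrix is replaced by its
nearest positive-(semi)definite neighbour via Higham's alternating
projections, with the unit diagonal restored at every iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ssrherit.genotype_io import (
    MISSING,
    AlleleFrequencyTable,
    GenotypeTable,
    allele_frequencies,
)

ESTIMATORS = ("qg", "li", "lr", "wang")

_DEN_TOL = 1e-12


@dataclass
class RelatednessMatrix:
    """Symmetric pairwise relatedness values for a set of unique genotypes.

    ``n_filled`` counts pairs whose estimator value was undefined (no
    usable locus or singular moment system) and was filled with 0, the
    unrelated-pair expectation.  ``psd`` is set by :func:`near_pd`.
    """

    ids: list[str]
    values: np.ndarray
    estimator: str
    psd: bool = False
    n_filled: int = 0
    skipped_loci: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} != ({n}, {n})")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("relatedness matrix is not symmetric")
        self.values = v

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def _locus_arrays(
    g: GenotypeTable, f: AlleleFrequencyTable, locus_idx: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray] | None:
    """Counts matrix C (n x K), freq vector p, typed mask, hom mask."""
    name = g.locus_names[locus_idx]
    alleles, p = f.arrays(name)
    col = g.calls[:, locus_idx, :]
    typed = (col != MISSING).all(axis=1)
    observed = set(int(a) for a in np.unique(col[col != MISSING]))
    unknown = observed - set(int(a) for a in alleles)
    if unknown:
        raise ValueError(
            f"locus {name!r}: alleles {sorted(unknown)[:5]} absent from the "
            "frequency table"
        )
    if len(alleles) < 2:
        return None  # monomorphic locus carries no relatedness information
    lookup = {int(a): k for k, a in enumerate(alleles)}
    n = g.n_individuals
    c = np.zeros((n, len(alleles)))
    for i in np.flatnonzero(typed):
        c[i, lookup[int(col[i, 0])]] += 1
        c[i, lookup[int(col[i, 1])]] += 1
    hom = (col[:, 0] == col[:, 1]) & typed
    return c, p, typed, hom


def _symmetrize_ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """Directional ratio-of-sums, averaged over reference directions."""
    with np.errstate(invalid="ignore", divide="ignore"):
        r_dir = np.where(np.abs(den) > _DEN_TOL, num / den, np.nan)
    both = np.isfinite(r_dir) & np.isfinite(r_dir.T)
    one = np.isfinite(r_dir) & ~np.isfinite(r_dir.T)
    out = np.full(num.shape, np.nan)
    out[both] = 0.5 * (r_dir + r_dir.T)[both]
    out[one] = r_dir[one]
    out[one.T] = r_dir.T[one.T]
    return out


def _qg(g, f):
    n = g.n_individuals
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    skipped: dict[str, int] = {}
    for j in range(g.n_loci):
        arrs = _locus_arrays(g, f, j)
        if arrs is None:
            continue
        c, p, typed, hom = arrs
        s = c @ c.T  # sum of allele-identity indicators over the 4 slot pairs
        px = c @ p
        den_x = 1.0 + hom.astype(float) - px  # row-constant, reference = x
        pair_ok = typed[:, None] & typed[None, :]
        ok_x = pair_ok & (np.abs(den_x)[:, None] > _DEN_TOL)
        skipped[g.locus_names[j]] = int(
            (typed & (np.abs(den_x) <= _DEN_TOL)).sum()
        )
        num += np.where(ok_x, 0.5 * s - px[:, None], 0.0)
        den += np.where(ok_x, den_x[:, None], 0.0)
    return _symmetrize_ratio(num, den), skipped


def _li(g, f):
    n = g.n_individuals
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for j in range(g.n_loci):
        arrs = _locus_arrays(g, f, j)
        if arrs is None:
            continue
        c, p, typed, _ = arrs
        present = (c > 0).astype(float)
        frac = (c @ present.T) / 2.0  # fraction of row copies present in col
        s = 0.5 * (frac + frac.T)
        a2 = float((p**2).sum())
        a3 = float((p**3).sum())
        s0 = 2.0 * a2 - a3
        if 1.0 - s0 <= _DEN_TOL:
            continue
        pair_ok = typed[:, None] & typed[None, :]
        num += np.where(pair_ok, s - s0, 0.0)
        den += np.where(pair_ok, 1.0 - s0, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > _DEN_TOL, num / den, np.nan), {}


def _lr(g, f, equal_locus_weights: bool):
    n = g.n_individuals
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    skipped: dict[str, int] = {}
    for j in range(g.n_loci):
        arrs = _locus_arrays(g, f, j)
        if arrs is None:
            continue
        c, p, typed, hom = arrs
        col = g.calls[:, j, :]
        K = c.shape[1]
        alleles, _ = f.arrays(g.locus_names[j])
        lookup = {int(a): k for k, a in enumerate(alleles)}
        # v_x(i): cross-weighted counts so that v_x . cnt_y gives
        # p_a*(d_bc+d_bd) + p_b*(d_ac+d_ad)
        v = np.zeros((n, K))
        papb = np.zeros(n)
        pab_sum = np.zeros(n)
        for i in np.flatnonzero(typed):
            a, b = int(col[i, 0]), int(col[i, 1])
            ka, kb = lookup[a], lookup[b]
            v[i, ka] += p[kb]
            v[i, kb] += p[ka]
            papb[i] = p[ka] * p[kb]
            pab_sum[i] = p[ka] + p[kb]
        num_x = v @ c.T - 4.0 * papb[:, None]
        den_x = (1.0 + hom.astype(float)) * pab_sum - 4.0 * papb
        pair_ok = typed[:, None] & typed[None, :]
        if equal_locus_weights:
            ok_x = pair_ok & (np.abs(den_x)[:, None] > _DEN_TOL)
            with np.errstate(invalid="ignore", divide="ignore"):
                num += np.where(ok_x, num_x / den_x[:, None], 0.0)
            den += ok_x
        else:
            # published weights w = den/(2 p_a p_b): the weighted mean of
            # per-locus ratios telescopes to sums of num/(2papb), den/(2papb)
            scale = np.where(papb > _DEN_TOL, 1.0 / (2.0 * papb), 0.0)
            ok_x = pair_ok & (papb[:, None] > _DEN_TOL)
            num += np.where(ok_x, num_x * scale[:, None], 0.0)
            den += np.where(ok_x, (den_x * scale)[:, None], 0.0)
        skipped[g.locus_names[j]] = int((typed & ~(np.abs(den_x) > _DEN_TOL)).sum())
    return _symmetrize_ratio(num, den), skipped


def wang_class_coefficients(p: np.ndarray) -> tuple[float, ...]:
    """Genotype-similarity class probabilities for Wang's moment model.

    Returns ``(b, c, d, e, f, g)`` where, for a dyad with two-gene IBD
    coefficient phi and four-gene coefficient Delta,

    * P(identical genotypes)        = b + c*phi + (1-b)*Delta
    * P(hom vs het sharing)         = d + e*phi - d*Delta
    * P(two hets sharing 1 allele)  = f + g*phi - f*Delta
    """
    a2 = float((p**2).sum())
    a3 = float((p**3).sum())
    a4 = float((p**4).sum())
    b = 2.0 * a2**2 - a4
    c = a2 - b
    d = 4.0 * (a3 - a4)
    e = 2.0 * (a2 - a3) - d
    f = 4.0 * (a2 - a2**2 - 2.0 * a3 + 2.0 * a4)
    g = 1.0 - 7.0 * a2 + 4.0 * a2**2 + 10.0 * a3 - 8.0 * a4
    return b, c, d, e, f, g


def _wang(g, f):
    n = g.n_individuals
    a11 = np.zeros((n, n))
    a12 = np.zeros((n, n))
    a22 = np.zeros((n, n))
    r1 = np.zeros((n, n))
    r2 = np.zeros((n, n))
    for j in range(g.n_loci):
        arrs = _locus_arrays(g, f, j)
        if arrs is None:
            continue
        c, p, typed, hom = arrs
        b, cc, d, e, ff, gg = wang_class_coefficients(p)
        z = (c > 0).astype(float)
        t = z @ z.T  # number of shared allele types
        both_hom = hom[:, None] & hom[None, :]
        both_het = (~hom & typed)[:, None] & (~hom & typed)[None, :]
        one_hom = (hom[:, None] ^ hom[None, :])
        p1 = (both_hom & (t == 1)) | (both_het & (t == 2))
        p2 = one_hom & (t == 1)
        p3 = both_het & (t == 1)
        pair_ok = (typed[:, None] & typed[None, :]).astype(float)
        p1 = p1.astype(float)
        p2 = p2.astype(float)
        p3 = p3.astype(float)
        a11 += (cc**2 + e**2 + gg**2) * pair_ok
        a12 += (cc * (1.0 - b) - e * d - gg * ff) * pair_ok
        a22 += ((1.0 - b) ** 2 + d**2 + ff**2) * pair_ok
        r1 += pair_ok * (cc * (p1 - b) + e * (p2 - d) + gg * (p3 - ff))
        r2 += pair_ok * ((1.0 - b) * (p1 - b) - d * (p2 - d) - ff * (p3 - ff))
    det = a11 * a22 - a12**2
    scale = np.maximum(a11 * a22, 1e-300)
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = (r1 * a22 - r2 * a12) / det
        delta = (a11 * r2 - a12 * r1) / det
        r = 0.5 * phi + delta
    r[np.abs(det) <= 1e-10 * scale] = np.nan
    return r, {}


def pairwise_relatedness(
    g: GenotypeTable,
    f: AlleleFrequencyTable | None = None,
    estimator: str = "lr",
    equal_locus_weights: bool = False,
    fill_missing: bool = True,
) -> RelatednessMatrix:
    """Pairwise relatedness matrix under one of the four estimators.

    Parameters
    ----------
    g
        Clone-filtered genotype table (one representative per genet).
    f
        Allele frequencies; defaults to the sample frequencies of ``g``.
    estimator
        One of ``"qg"``, ``"li"``, ``"lr"``, ``"wang"``.
    equal_locus_weights
        For ``lr``, use a simple average over loci instead of the
        published inverse-variance weights.
    fill_missing
        Replace undefined pair values with 0 (the unrelated-pair
        expectation); the number of filled cells is recorded.
    """
    estimator = estimator.lower()
    if estimator not in ESTIMATORS:
        raise ValueError(f"unknown estimator {estimator!r}; expected {ESTIMATORS}")
    if f is None:
        f = allele_frequencies(g)
    if estimator == "qg":
        r, skipped = _qg(g, f)
    elif estimator == "li":
        r, skipped = _li(g, f)
    elif estimator == "lr":
        r, skipped = _lr(g, f, equal_locus_weights)
    else:
        r, skipped = _wang(g, f)
    np.fill_diagonal(r, 1.0)
    n_filled = 0
    if fill_missing:
        bad = ~np.isfinite(r)
        n_filled = int(bad.sum() // 2)
        r[bad] = 0.0
    r = 0.5 * (r + r.T)  # exact numerical symmetry
    np.fill_diagonal(r, 1.0)
    return RelatednessMatrix(
        list(g.ids), r, estimator, n_filled=n_filled,
        skipped_loci={k: v for k, v in skipped.items() if v},
    )


def set_diagonal_unity(m: RelatednessMatrix) -> RelatednessMatrix:
    """Return a copy with the diagonal set exactly to 1 (self-relatedness)."""
    v = m.values.copy()
    np.fill_diagonal(v, 1.0)
    return RelatednessMatrix(
        list(m.ids), v, m.estimator, psd=False,
        n_filled=m.n_filled, skipped_loci=dict(m.skipped_loci),
    )


def near_pd(
    m: RelatednessMatrix,
    eps: float = 1e-8,
    tol: float = 1e-10,
    max_iter: int = 600,
) -> RelatednessMatrix:
    """Nearest positive-(semi)definite matrix with unit diagonal.

    Higham's alternating projections between the PSD cone and the
    unit-diagonal affine set, with Dykstra's correction; after
    convergence the smallest eigenvalue is floored at ``eps`` and the
    diagonal renormalized.  Idempotent on already-conforming input.
    """
    a = m.values.copy()
    if not np.allclose(a, a.T):
        raise ValueError("input must be symmetric")
    n = a.shape[0]
    y = a.copy()
    ds = np.zeros_like(a)
    converged = False
    for it in range(1, max_iter + 1):
        r = y - ds
        w, v = np.linalg.eigh(0.5 * (r + r.T))
        x = (v * np.clip(w, 0.0, None)) @ v.T
        ds = x - r
        y_new = x.copy()
        np.fill_diagonal(y_new, 1.0)
        delta = np.max(np.abs(y_new - y)) / max(np.max(np.abs(y_new)), 1.0)
        y = y_new
        if delta <= tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(
            f"near_pd did not converge within {max_iter} iterations "
            f"(last relative change {delta:.2e})"
        )
    w, v = np.linalg.eigh(0.5 * (y + y.T))
    if w[0] < eps:
        y = (v * np.maximum(w, eps)) @ v.T
        d = np.sqrt(np.diag(y))
        y = y / np.outer(d, d)
    y = 0.5 * (y + y.T)
    np.fill_diagonal(y, 1.0)
    return RelatednessMatrix(
        list(m.ids), y, m.estimator, psd=True,
        n_filled=m.n_filled, skipped_loci=dict(m.skipped_loci),
    )
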