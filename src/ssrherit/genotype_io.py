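"""Reading, validating and summarizing diploid SSR genotype tables.

Two on-disk representations are supported:

* **GENEPOP** text files, the population-genetics lingua franca: a title
  line, locus names (one per line or a single comma-separated line), and
  ``POP`` blocks of individuals with concatenated 2- or 3-digit allele
  codes (``0``/``00``/``000`` meaning a missing allele).  Both the
  canonical ``id , 101103 ...`` row form and the whitespace-only dialect
  without the comma are accepted.
* a **delimited table** with columns ``id``, optionally ``site``, then a
  pair of columns ``<locus>_a1``/``<locus>_a2`` per locus.

Missing calls are preserved as missing throughout; nothing is imputed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = 0  # allele code marking a missing gene copy


class GenotypeFormatError(ValueError):
    """Raised for malformed genotype files; message names the offending line."""


@dataclass(frozen=True)
class Locus:
    """A codominant SSR locus: a name and its set of allele sizes (bp)."""

    name: str
    alleles: frozenset[int]

    def __post_init__(self) -> None:
        if len(self.alleles) < 1:
            raise ValueError(f"locus {self.name!r} has no alleles")
        if any(a <= 0 for a in self.alleles):
            raise ValueError(f"locus {self.name!r} has non-positive allele sizes")


class GenotypeTable:
    """Individuals x loci diploid allele-size calls with explicit missing data.

    Parameters
    ----------
    ids
        Unique individual (patch) identifiers, order preserved.
    locus_names
        Locus labels, order preserved.
    calls
        Integer array of shape ``(n_individuals, n_loci, 2)``; a missing
        call is encoded as ``(0, 0)``.  Within-cell allele order is
        normalized to ascending, so the pair is unordered.
    sites
        Optional per-individual site labels (carried through to the
        delimited-table writer).
    """

    def __init__(
        self,
        ids: Sequence[str],
        locus_names: Sequence[str],
        calls: np.ndarray,
        sites: Sequence[str] | None = None,
    ) -> None:
        ids = [str(i) for i in ids]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate individual ids: {dupes[:5]}")
        calls = np.asarray(calls, dtype=np.int64)
        if calls.shape != (len(ids), len(locus_names), 2):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"({len(ids)}, {len(locus_names)}, 2)"
            )
        if (calls < 0).any():
            raise ValueError("negative allele codes")
        # a call with any missing gene copy is treated as a missing call
        half_missing = (calls == MISSING).any(axis=2) & ~(calls == MISSING).all(axis=2)
        if half_missing.any():
            calls = calls.copy()
            calls[half_missing] = MISSING
        self.ids = list(ids)
        self.calls = np.sort(calls, axis=2)
        self.sites = list(sites) if sites is not None else None
        if self.sites is not None and len(self.sites) != len(self.ids):
            raise ValueError("sites length does not match ids")
        self.loci = [
            self._make_locus(name, self.calls[:, j, :])
            for j, name in enumerate(locus_names)
        ]

    @staticmethod
    def _make_locus(name: str, col: np.ndarray) -> Locus:
        observed = frozenset(int(a) for a in np.unique(col) if a != MISSING)
        if not observed:
            # entirely-missing locus: keep a placeholder allele set so the
            # table stays constructible; summaries will refuse it explicitly
            return Locus(name, frozenset({1}))
        return Locus(name, observed)

    # -- basic protocol ---------------------------------------------------
    @property
    def locus_names(self) -> list[str]:
        return [l.name for l in self.loci]

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def missing_mask(self) -> np.ndarray:
        """Boolean ``(n, L)`` array, True where the call is missing."""
        return (self.calls == MISSING).all(axis=2)

    def n_missing(self) -> int:
        return int(self.missing_mask().sum())

    def subset(self, keep_ids: Iterable[str]) -> "GenotypeTable":
        """Return a new table restricted to ``keep_ids`` (original order kept)."""
        keep = set(keep_ids)
        idx = [i for i, x in enumerate(self.ids) if x in keep]
        missing = keep - {self.ids[i] for i in idx}
        if missing:
            raise KeyError(f"unknown ids: {sorted(missing)[:5]}")
        return GenotypeTable(
            [self.ids[i] for i in idx],
            self.locus_names,
            self.calls[idx],
            [self.sites[i] for i in idx] if self.sites is not None else None,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            self.ids == other.ids
            and self.locus_names == other.locus_names
            and np.array_equal(self.calls, other.calls)
        )

    def __repr__(self) -> str:
        return (
            f"GenotypeTable({self.n_individuals} individuals, "
            f"{self.n_loci} loci, {self.n_missing()} missing calls)"
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Delimited-table representation (id, site, then <locus>_a1/_a2)."""
        data: dict[str, object] = {"id": self.ids}
        if self.sites is not None:
            data["site"] = self.sites
        for j, name in enumerate(self.locus_names):
            data[f"{name}_a1"] = self.calls[:, j, 0]
            data[f"{name}_a2"] = self.calls[:, j, 1]
        return pd.DataFrame(data)


@dataclass
class AlleleFrequencyTable:
    """Per-locus allele-size -> frequency maps (summing to 1 per locus)."""

    freqs: dict[str, dict[int, float]]
    n_copies: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for locus, f in self.freqs.items():
            total = sum(f.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"locus {locus!r} frequencies sum to {total}")
            if any(p < 0 for p in f.values()):
                raise ValueError(f"locus {locus!r} has negative frequencies")

    @property
    def locus_names(self) -> list[str]:
        return list(self.freqs)

    def arrays(self, locus: str) -> tuple[np.ndarray, np.ndarray]:
        """Sorted allele sizes and matching frequency vector for one locus."""
        f = self.freqs[locus]
        alleles = np.array(sorted(f), dtype=np.int64)
        return alleles, np.array([f[a] for a in alleles])

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"locus": locus, "allele": a, "freq": p}
            for locus, f in self.freqs.items()
            for a, p in sorted(f.items())
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# GENEPOP reader / writer
# ---------------------------------------------------------------------------

_POP_RE = re.compile(r"^\s*pop\s*$", re.IGNORECASE)


def _split_genotype_token(token: str, lineno: int) -> tuple[int, int]:
    if not token.isdigit() or len(token) not in (4, 6):
        raise GenotypeFormatError(
            f"line {lineno}: genotype token {token!r} is not 4 or 6 digits"
        )
    w = len(token) // 2
    return int(token[:w]), int(token[w:])


def _read_genepop(path: Path) -> GenotypeTable:
    lines = path.read_text().splitlines()
    if not any(line.strip() for line in lines):
        raise GenotypeFormatError("no individuals: file is empty")
    # title line is free text and skipped
    locus_names: list[str] = []
    i = 1
    while i < len(lines) and not _POP_RE.match(lines[i]):
        chunk = lines[i].strip()
        if chunk:
            locus_names.extend(n.strip() for n in chunk.split(",") if n.strip())
        i += 1
    if i == len(lines):
        raise GenotypeFormatError("no POP line found")
    if not locus_names:
        raise GenotypeFormatError("no locus names before first POP line")

    ids: list[str] = []
    sites: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    pop_index = 0
    for lineno0, line in enumerate(lines[i:], start=i):
        if _POP_RE.match(line):
            pop_index += 1
            continue
        if not line.strip():
            continue
        lineno = lineno0 + 1
        if "," in line:
            ind_id, _, rest = line.partition(",")
            ind_id = ind_id.strip()
            tokens = rest.split()
        else:  # whitespace dialect: first token is the id
            parts = line.split()
            ind_id, tokens = parts[0], parts[1:]
        if not ind_id:
            raise GenotypeFormatError(f"line {lineno}: empty individual id")
        if len(tokens) != len(locus_names):
            raise GenotypeFormatError(
                f"line {lineno}: expected {len(locus_names)} genotypes, "
                f"got {len(tokens)}"
            )
        rows.append([_split_genotype_token(t, lineno) for t in tokens])
        ids.append(ind_id)
        sites.append(f"pop{pop_index}")
    if not ids:
        raise GenotypeFormatError("no individuals: no genotype rows after POP")
    calls = np.array(rows, dtype=np.int64)
    return GenotypeTable(ids, locus_names, calls, sites)


def _write_genepop(g: GenotypeTable, path: Path, digits: int = 3) -> None:
    out = ["ssrherit genotype export"]
    out.extend(g.locus_names)
    out.append("POP")
    for i, ind in enumerate(g.ids):
        tokens = [
            f"{a1:0{digits}d}{a2:0{digits}d}" for a1, a2 in g.calls[i]
        ]
        out.append(f"{ind} , " + " ".join(tokens))
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# delimited table reader / writer
# ---------------------------------------------------------------------------


def _read_table(path: Path) -> GenotypeTable:
    df = pd.read_csv(path, sep=None, engine="python")
    if df.empty:
        raise GenotypeFormatError("no individuals: table has no rows")
    cols = list(df.columns)
    if "id" not in cols:
        raise GenotypeFormatError("table must have an 'id' column")
    pair_cols = [c for c in cols if c.endswith("_a1")]
    locus_names = [c[:-3] for c in pair_cols]
    for name in locus_names:
        if f"{name}_a2" not in cols:
            raise GenotypeFormatError(f"locus {name!r}: missing column {name}_a2")
    if not locus_names:
        raise GenotypeFormatError("no <locus>_a1/<locus>_a2 column pairs found")
    calls = np.zeros((len(df), len(locus_names), 2), dtype=np.int64)
    for j, name in enumerate(locus_names):
        for k, suffix in enumerate(("_a1", "_a2")):
            col = pd.to_numeric(df[f"{name}{suffix}"], errors="coerce")
            calls[:, j, k] = col.fillna(MISSING).astype(np.int64).to_numpy()
    sites = df["site"].astype(str).tolist() if "site" in cols else None
    return GenotypeTable(df["id"].astype(str).tolist(), locus_names, calls, sites)


def _write_table(g: GenotypeTable, path: Path) -> None:
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    g.to_dataframe().to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def read_genotypes(path: str | Path, format: str = "genepop") -> GenotypeTable:
    """Read a genotype file in ``genepop`` or ``table`` format.

    Missing calls (GENEPOP code 0/00/000, or empty cells in the table
    form) are preserved as missing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "genepop":
        return _read_genepop(path)
    if format == "table":
        return _read_table(path)
    raise ValueError(f"unknown format {format!r} (expected 'genepop' or 'table')")


def write_genotypes(g: GenotypeTable, path: str | Path, format: str = "genepop") -> None:
    """Write a :class:`GenotypeTable` in ``genepop`` or ``table`` format."""
    path = Path(path)
    if format == "genepop":
        digits = 3 if max(max(l.alleles) for l in g.loci) > 99 else 2
        _write_genepop(g, path, digits=digits)
    elif format == "table":
        _write_table(g, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def allele_frequencies(g: GenotypeTable) -> AlleleFrequencyTable:
    """Sample allele frequencies, counting each non-missing call as 2 copies.

    Raises if a locus has no non-missing calls at all.
    """
    freqs: dict[str, dict[int, float]] = {}
    n_copies: dict[str, int] = {}
    for j, name in enumerate(g.locus_names):
        col = g.calls[:, j, :]
        observed = col[col != MISSING]
        if observed.size == 0:
            raise ValueError(f"locus {name!r} is entirely missing")
        alleles, counts = np.unique(observed, return_counts=True)
        total = counts.sum()
        freqs[name] = {int(a): float(c) / total for a, c in zip(alleles, counts)}
        n_copies[name] = int(total)
    return AlleleFrequencyTable(freqs, n_copies)


def locus_summary(g: GenotypeTable) -> pd.DataFrame:
    """Per-locus diversity summary.

    Columns: ``n_alleles``; observed heterozygosity ``Ho``; expected
    (Nei gene diversity) ``He = 1 - sum(p_i^2)``; effective number of
    alleles ``Ae = 1 / sum(p_i^2)``; ``n_typed`` individuals.
    """
    f = allele_frequencies(g)
    rows = []
    for j, name in enumerate(g.locus_names):
        _, p = f.arrays(name)
        col = g.calls[:, j, :]
        typed = (col != MISSING).all(axis=1)
        het = col[typed, 0] != col[typed, 1]
        sum_p2 = float((p**2).sum())
        rows.append(
            {
                "locus": name,
                "n_alleles": len(p),
                "n_typed": int(typed.sum()),
                "Ho": float(het.mean()) if typed.any() else np.nan,
                "He": 1.0 - sum_p2,
                "Ae": 1.0 / sum_p2,
            }
        )
    return pd.DataFrame(rows).set_index("locus")
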