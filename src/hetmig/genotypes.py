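"""Genotype tables for co-dominant microsatellite panels.

The central container is :class:`GenotypeTable`: individuals x loci, two
allele labels per call, with a single internal missing marker.  Allele
labels are opaque strings -- fragment sizes ("152"), letters ("A") and
arbitrary codes all behave identically and are never interpreted
numerically.

Two on-disk dialects are supported:

* a wide CSV with header ``id,group,<locus>_a,<locus>_b,...``
* a GenePop-style text file (title line, locus names, ``Pop`` blocks,
  2- or 3-digit allele codes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "GenotypeTable",
    "GenotypeParseError",
    "read_genotype_table",
    "write_genotype_table",
]

#: Internal missing-allele marker.  All recognised missing codes are
#: normalised to this on input.
MISSING: Optional[str] = None

_MISSING_CODES = {"", "0", "00", "000", "0000", "000000", "NA", "na", "NaN", "nan", "."}


class GenotypeParseError(ValueError):
    """Raised for malformed genotype files; carries the offending line number."""

    def __init__(self, message: str, line: Optional[int] = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


def _norm_allele(code: str) -> Optional[str]:
    code = code.strip()
    return None if code in _MISSING_CODES else code


@dataclass
class GenotypeTable:
    """Individuals x loci genotype calls with optional group labels.

    ``calls`` is an object array of shape ``(n_individuals, n_loci, 2)``
    holding allele labels (str) or ``None``; both slots of a call are
    either present or missing, never mixed.
    """

    individual_ids: list[str]
    locus_names: list[str]
    calls: np.ndarray
    group: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.individual_ids = [str(i) for i in self.individual_ids]
        self.locus_names = [str(l) for l in self.locus_names]
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("duplicate individual ids")
        if len(set(self.locus_names)) != len(self.locus_names):
            raise ValueError("duplicate locus names")
        self.calls = np.asarray(self.calls, dtype=object)
        if self.calls.shape != (len(self.individual_ids), len(self.locus_names), 2):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.individual_ids)} individuals x {len(self.locus_names)} loci"
            )
        half = (self.calls == None).sum(axis=2)  # noqa: E711 -- elementwise
        if np.any(half == 1):
            i, l = np.argwhere(half == 1)[0]
            raise ValueError(
                f"half-missing call for individual {self.individual_ids[i]} "
                f"at locus {self.locus_names[l]}"
            )
        if self.group is not None:
            if len(self.group) != len(self.individual_ids):
                raise ValueError("group labels must match number of individuals")
            self.group = [str(g) for g in self.group]

    # -- basic shape ---------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    def missing_mask(self) -> np.ndarray:
        """Boolean (n_individuals, n_loci); True where the call is missing."""
        return self.calls[:, :, 0] == None  # noqa: E711

    def completeness(self) -> float:
        """Fraction of (individual, locus) cells with a typed call."""
        return float(1.0 - self.missing_mask().mean())

    # -- indexing helpers ----------------------------------------------
    def locus_index(self, locus: str) -> int:
        try:
            return self.locus_names.index(locus)
        except ValueError:
            raise KeyError(f"unknown locus {locus!r}") from None

    def subset(self, individuals: Sequence[str]) -> "GenotypeTable":
        idx = [self.individual_ids.index(str(i)) for i in individuals]
        return GenotypeTable(
            [self.individual_ids[i] for i in idx],
            list(self.locus_names),
            self.calls[idx].copy(),
            None if self.group is None else [self.group[i] for i in idx],
        )

    def groups(self) -> dict[str, list[str]]:
        if self.group is None:
            raise ValueError("table has no group labels")
        out: dict[str, list[str]] = {}
        for ind, g in zip(self.individual_ids, self.group):
            out.setdefault(g, []).append(ind)
        return out

    def encoded(self, locus: str) -> tuple[np.ndarray, np.ndarray, list[str]]:
        """Integer-encode one locus.

        Returns ``(codes, typed, alleles)`` where ``codes`` is
        ``(n_individuals, 2)`` int (−1 where missing), ``typed`` the
        non-missing mask and ``alleles`` the sorted label list.
        """
        j = self.locus_index(locus)
        col = self.calls[:, j, :]
        typed = col[:, 0] != None  # noqa: E711
        alleles = sorted({a for row in col[typed] for a in row})
        lut = {a: k for k, a in enumerate(alleles)}
        codes = np.full((self.n_individuals, 2), -1, dtype=int)
        for i in np.nonzero(typed)[0]:
            codes[i, 0] = lut[col[i, 0]]
            codes[i, 1] = lut[col[i, 1]]
        return codes, typed, alleles


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def _read_csv(path: Path) -> GenotypeTable:
    df = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    cols = list(df.columns)
    if not cols or cols[0] != "id":
        raise GenotypeParseError("first CSV column must be 'id'", line=1)
    has_group = len(cols) > 1 and cols[1] == "group"
    allele_cols = cols[2:] if has_group else cols[1:]
    if len(allele_cols) % 2 != 0:
        raise GenotypeParseError(
            f"odd number of allele columns ({len(allele_cols)})", line=1
        )
    loci: list[str] = []
    for a_col, b_col in zip(allele_cols[0::2], allele_cols[1::2]):
        if not (a_col.endswith("_a") and b_col.endswith("_b") and a_col[:-2] == b_col[:-2]):
            raise GenotypeParseError(
                f"allele columns must pair as '<locus>_a','<locus>_b'; got {a_col!r},{b_col!r}",
                line=1,
            )
        loci.append(a_col[:-2])
    ids = df["id"].tolist()
    seen: set[str] = set()
    for r, ind in enumerate(ids):
        if ind in seen:
            raise GenotypeParseError(f"duplicate individual id {ind!r}", line=r + 2)
        seen.add(ind)
    calls = np.empty((len(ids), len(loci), 2), dtype=object)
    for j, locus in enumerate(loci):
        a = df[f"{locus}_a"].map(_norm_allele)
        b = df[f"{locus}_b"].map(_norm_allele)
        for r in range(len(ids)):
            aa, bb = a.iat[r], b.iat[r]
            if (aa is None) != (bb is None):
                raise GenotypeParseError(
                    f"half-missing call at locus {locus} for id {ids[r]}", line=r + 2
                )
            calls[r, j, 0] = aa
            calls[r, j, 1] = bb
    group = df["group"].tolist() if has_group else None
    return GenotypeTable(ids, loci, calls, group)


def _write_csv(g: GenotypeTable, path: Path) -> None:
    data: dict[str, list] = {"id": g.individual_ids}
    if g.group is not None:
        data["group"] = g.group
    for j, locus in enumerate(g.locus_names):
        data[f"{locus}_a"] = ["" if a is None else a for a in g.calls[:, j, 0]]
        data[f"{locus}_b"] = ["" if a is None else a for a in g.calls[:, j, 1]]
    pd.DataFrame(data).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# GenePop dialect
# ---------------------------------------------------------------------------

def _read_genepop(path: Path) -> GenotypeTable:
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise GenotypeParseError("GenePop file too short", line=1)
    # locus names: one per line, or comma-separated on one line
    loci: list[str] = []
    body_start = None
    for k, line in enumerate(lines[1:], start=2):
        if line.strip().lower() == "pop":
            body_start = k
            break
        for name in line.split(","):
            name = name.strip()
            if name:
                loci.append(name)
    if body_start is None:
        raise GenotypeParseError("no 'Pop' line found")
    if not loci:
        raise GenotypeParseError("no locus names before first 'Pop'", line=2)

    ids: list[str] = []
    groups: list[str] = []
    rows: list[list[Optional[str]]] = []
    pop_idx = 0
    for k, line in enumerate(lines[body_start - 1:], start=body_start):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.lower() == "pop":
            pop_idx += 1
            continue
        if "," not in stripped:
            raise GenotypeParseError("sample line missing ',' separator", line=k)
        ind, geno = stripped.split(",", 1)
        ind = ind.strip()
        if ind in ids:
            raise GenotypeParseError(f"duplicate individual id {ind!r}", line=k)
        fields = geno.split()
        if len(fields) != len(loci):
            raise GenotypeParseError(
                f"expected {len(loci)} genotype fields, got {len(fields)}", line=k
            )
        row: list[Optional[str]] = []
        for f in fields:
            if len(f) not in (4, 6) or not f.isdigit():
                raise GenotypeParseError(f"bad genotype field {f!r}", line=k)
            w = len(f) // 2
            row.extend([_norm_allele(f[:w]), _norm_allele(f[w:])])
        ids.append(ind)
        groups.append(f"pop{pop_idx}")
        rows.append(row)
    if not ids:
        raise GenotypeParseError("no samples found")
    calls = np.array(rows, dtype=object).reshape(len(ids), len(loci), 2)
    # normalise half-missing (e.g. "000152") to fully missing
    for i in range(len(ids)):
        for j in range(len(loci)):
            if (calls[i, j, 0] is None) != (calls[i, j, 1] is None):
                calls[i, j, 0] = calls[i, j, 1] = None
    return GenotypeTable(ids, loci, calls, groups)


def _write_genepop(g: GenotypeTable, path: Path, title: str = "hetmig export") -> None:
    # map allele labels to 3-digit codes per locus (numeric labels kept if they fit)
    luts: list[dict[str, str]] = []
    for j, locus in enumerate(g.locus_names):
        labels = sorted({a for a in g.calls[:, j, :].ravel() if a is not None})
        if all(lbl.isdigit() and 0 < int(lbl) <= 999 for lbl in labels):
            lut = {lbl: f"{int(lbl):03d}" for lbl in labels}
        else:
            lut = {lbl: f"{k + 1:03d}" for k, lbl in enumerate(labels)}
        luts.append(lut)
    out = [title]
    out.extend(g.locus_names)
    blocks: dict[str, list[int]] = {}
    if g.group is None:
        blocks["all"] = list(range(g.n_individuals))
    else:
        for i, grp in enumerate(g.group):
            blocks.setdefault(grp, []).append(i)
    for members in blocks.values():
        out.append("Pop")
        for i in members:
            fields = []
            for j in range(g.n_loci):
                a, b = g.calls[i, j, :]
                fields.append("000000" if a is None else luts[j][a] + luts[j][b])
            out.append(f"{g.individual_ids[i]} ,  " + " ".join(fields))
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------

def read_genotype_table(path, dialect: str = "csv") -> GenotypeTable:
    """Read a genotype file.

    Parameters
    ----------
    path
        Input file.
    dialect
        ``"csv"`` (wide, ``id,group,<locus>_a,<locus>_b,...``) or
        ``"genepop"``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "csv":
        return _read_csv(path)
    if dialect == "genepop":
        return _read_genepop(path)
    raise GenotypeParseError(f"unknown dialect {dialect!r}")


def write_genotype_table(g: GenotypeTable, path, dialect: str = "csv") -> None:
    """Write a genotype table in the requested dialect (see
    :func:`read_genotype_table`)."""
    path = Path(path)
    if dialect == "csv":
        _write_csv(g, path)
    elif dialect == "genepop":
        _write_genepop(g, path)
    else:
        raise GenotypeParseError(f"unknown dialect {dialect!r}")
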