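"""Clonotype tables: reading, writing, filtering and depth normalization.

Clonotype tables are tab-separated files with one row per unique CDR3
nucleotide rearrangement. Column names default to the AIRR rearrangement
schema (``junction``, ``v_call``, ``j_call``, ``duplicate_count``,
``productive``, ``v_identity``) and can be remapped for other exporters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DepthError, FormatError, RowParseError, ValidationError

LOCI = ("TRB", "IGH")

#: logical field -> AIRR rearrangement schema column
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "cdr3_nt": "junction",
    "cdr3_aa": "junction_aa",
    "v_gene": "v_call",
    "j_gene": "j_call",
    "read_count": "duplicate_count",
    "productive": "productive",
    "v_identity_pct": "v_identity",
}

#: columns that must be present in every input table
_REQUIRED_FIELDS = ("cdr3_nt", "v_gene", "j_gene", "read_count", "productive")

_TRUTHY = {"t", "true", "1", "yes", "y"}
_FALSY = {"f", "false", "0", "no", "n", ""}


@dataclass
class Clonotype:
    """One unique CDR3-nucleotide rearrangement with its annotations."""

    cdr3_nt: str
    cdr3_aa: str = ""
    v_gene: str = ""
    j_gene: str = ""
    read_count: int = 1
    productive: bool = True
    v_identity_pct: float | None = None
    pgen: float | None = None

    def __post_init__(self):
        if not self.cdr3_nt:
            raise ValidationError("cdr3_nt must be non-empty")
        if self.read_count < 1:
            raise ValidationError(
                f"read_count must be >= 1, got {self.read_count} for {self.cdr3_nt}"
            )
        if self.v_identity_pct is not None and not (0.0 <= self.v_identity_pct <= 100.0):
            raise ValidationError(
                f"v_identity_pct must lie in [0, 100], got {self.v_identity_pct}"
            )
        if self.pgen is not None and not (0.0 <= self.pgen <= 1.0):
            raise ValidationError(f"pgen must lie in [0, 1], got {self.pgen}")


@dataclass
class Repertoire:
    """All clonotypes observed for one subject at one locus.

    ``clonotypes`` is keyed by CDR3 nucleotide sequence, the clone unit.
    ``normalized_to`` records the target depth of the last subsampling
    step (``None`` for raw repertoires); ``seed`` the RNG seed used.
    """

    subject_id: str
    locus: str
    clonotypes: dict[str, Clonotype] = field(default_factory=dict)
    normalized_to: int | None = None
    seed: int | None = None

    def __post_init__(self):
        if self.locus not in LOCI:
            raise ValidationError(f"locus must be one of {LOCI}, got {self.locus!r}")
        for key, clone in self.clonotypes.items():
            if key != clone.cdr3_nt:
                raise ValidationError(
                    f"clonotype key {key!r} does not match cdr3_nt {clone.cdr3_nt!r}"
                )

    @property
    def total_reads(self) -> int:
        return sum(c.read_count for c in self.clonotypes.values())

    @property
    def richness(self) -> int:
        return len(self.clonotypes)

    def sorted_clonotypes(self) -> list[Clonotype]:
        """Clonotypes in a canonical order: descending count, then cdr3_nt."""
        return sorted(
            self.clonotypes.values(), key=lambda c: (-c.read_count, c.cdr3_nt)
        )


def _parse_bool(raw: str, row: int, column: str) -> bool:
    token = str(raw).strip().lower()
    if token in _TRUTHY:
        return True
    if token in _FALSY:
        return False
    raise RowParseError(row, f"cannot interpret {raw!r} as boolean in column {column!r}")


def read_clonotype_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    locus: str = "TRB",
    subject_id: str | None = None,
) -> Repertoire:
    """Read a tab-separated clonotype table into a :class:`Repertoire`.

    Rows sharing the same CDR3 nucleotide sequence are merged by summing
    read counts; the V/J calls of the merged clone are the majority calls
    by read mass, ties broken lexicographically.

    Parameters
    ----------
    path
        Tab-separated file with a header row.
    column_map
        Overrides for :data:`DEFAULT_COLUMN_MAP` (logical field -> column
        name), e.g. for MiXCR ``exportClones`` headers.
    locus
        ``"TRB"`` or ``"IGH"``.
    subject_id
        Defaults to the file stem.
    """
    path = Path(path)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)

    table = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for logical in _REQUIRED_FIELDS:
        if cmap[logical] not in table.columns:
            raise FormatError(
                f"missing required column {cmap[logical]!r} (holds {logical}) in {path}"
            )
    has_aa = cmap["cdr3_aa"] in table.columns
    has_ident = cmap["v_identity_pct"] in table.columns

    # accumulate per-cdr3: total count, per-(v,j) mass, representative row
    merged: dict[str, dict] = {}
    for idx, row in enumerate(table.itertuples(index=False), start=2):
        rec = dict(zip(table.columns, row))
        cdr3 = rec[cmap["cdr3_nt"]].strip().upper()
        if not cdr3:
            raise RowParseError(idx, f"empty value in column {cmap['cdr3_nt']!r}")
        raw_count = rec[cmap["read_count"]].strip()
        try:
            count = int(raw_count)
        except ValueError:
            raise RowParseError(
                idx,
                f"non-integer read count {raw_count!r} in column {cmap['read_count']!r}",
            ) from None
        if count < 1:
            raise RowParseError(idx, f"read count must be >= 1, got {count}")
        productive = _parse_bool(rec[cmap["productive"]], idx, cmap["productive"])
        ident = None
        if has_ident and rec[cmap["v_identity_pct"]].strip() != "":
            try:
                ident = float(rec[cmap["v_identity_pct"]])
            except ValueError:
                raise RowParseError(
                    idx, f"non-numeric v identity {rec[cmap['v_identity_pct']]!r}"
                ) from None
        aa = rec[cmap["cdr3_aa"]].strip() if has_aa else ""

        slot = merged.setdefault(
            cdr3,
            {
                "count": 0,
                "v_mass": {},
                "j_mass": {},
                "aa": aa,
                "productive": productive,
                "ident_num": 0.0,
                "ident_mass": 0,
            },
        )
        slot["count"] += count
        slot["v_mass"][rec[cmap["v_gene"]]] = (
            slot["v_mass"].get(rec[cmap["v_gene"]], 0) + count
        )
        slot["j_mass"][rec[cmap["j_gene"]]] = (
            slot["j_mass"].get(rec[cmap["j_gene"]], 0) + count
        )
        slot["productive"] = slot["productive"] or productive
        if ident is not None:
            slot["ident_num"] += ident * count
            slot["ident_mass"] += count

    def majority(mass: dict[str, int]) -> str:
        # highest read mass wins; ties broken by lexicographic order
        return min(mass, key=lambda g: (-mass[g], g))

    clonotypes = {}
    for cdr3, slot in merged.items():
        ident = (
            slot["ident_num"] / slot["ident_mass"] if slot["ident_mass"] > 0 else None
        )
        clonotypes[cdr3] = Clonotype(
            cdr3_nt=cdr3,
            cdr3_aa=slot["aa"],
            v_gene=majority(slot["v_mass"]),
            j_gene=majority(slot["j_mass"]),
            read_count=slot["count"],
            productive=slot["productive"],
            v_identity_pct=ident,
        )

    return Repertoire(
        subject_id=subject_id or path.stem,
        locus=locus,
        clonotypes=clonotypes,
    )


def write_clonotype_table(rep: Repertoire, path: str | Path) -> None:
    """Write a repertoire as an AIRR-style rearrangement TSV."""
    rows = []
    for clone in rep.sorted_clonotypes():
        rows.append(
            {
                "junction": clone.cdr3_nt,
                "junction_aa": clone.cdr3_aa,
                "v_call": clone.v_gene,
                "j_call": clone.j_gene,
                "duplicate_count": clone.read_count,
                "productive": "T" if clone.productive else "F",
                "v_identity": "" if clone.v_identity_pct is None else repr(clone.v_identity_pct),
                "pgen": "" if clone.pgen is None else repr(clone.pgen),
            }
        )
    pd.DataFrame(rows, columns=list(rows[0]) if rows else list(DEFAULT_COLUMN_MAP.values()) + ["pgen"]).to_csv(
        path, sep="\t", index=False
    )


def filter_repertoire(
    rep: Repertoire, min_count: int = 2, productive_only: bool = True
) -> Repertoire:
    """Drop non-productive clonotypes and those below ``min_count`` reads.

    Returns a new repertoire; the input is left unmodified. An empty
    result is legal.
    """
    if min_count < 1:
        raise ValidationError(f"min_count must be >= 1, got {min_count}")
    kept = {
        key: replace(clone)
        for key, clone in rep.clonotypes.items()
        if clone.read_count >= min_count and (clone.productive or not productive_only)
    }
    return Repertoire(
        subject_id=rep.subject_id,
        locus=rep.locus,
        clonotypes=kept,
        normalized_to=rep.normalized_to,
        seed=rep.seed,
    )


def downsample_reads(
    rep: Repertoire,
    target: int,
    seed: int,
    with_replacement: bool = False,
) -> Repertoire:
    """Rarefy a repertoire to exactly ``target`` reads by seeded subsampling.

    Each clonotype contributes ``read_count`` indistinguishable reads to a
    pool from which ``target`` reads are drawn without replacement
    (multivariate hypergeometric); clonotypes receiving zero sampled reads
    are dropped. ``with_replacement=True`` switches to multinomial
    resampling instead of true rarefaction.

    Raises
    ------
    DepthError
        If the repertoire holds fewer than ``target`` reads. Exclusion
        policy for shallow repertoires belongs to the caller.
    """
    if target < 1:
        raise ValidationError(f"target must be >= 1, got {target}")
    total = rep.total_reads
    if total < target and not with_replacement:
        raise DepthError(total, target)

    clones = sorted(rep.clonotypes.values(), key=lambda c: c.cdr3_nt)
    counts = np.array([c.read_count for c in clones], dtype=np.int64)
    rng = np.random.default_rng(seed)
    if with_replacement:
        sampled = rng.multinomial(target, counts / counts.sum())
    else:
        sampled = rng.multivariate_hypergeometric(counts, target)

    kept = {}
    for clone, n in zip(clones, sampled):
        if n > 0:
            kept[clone.cdr3_nt] = replace(clone, read_count=int(n))
    return Repertoire(
        subject_id=rep.subject_id,
        locus=rep.locus,
        clonotypes=kept,
        normalized_to=target,
        seed=seed,
    )
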