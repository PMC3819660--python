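"""Subcellular partitioning of scaffolds from nucleotide-alignment hits.

Assembled scaffolds are assigned to the chloroplast, mitochondrial or
nuclear genome of origin by similarity to the organelle reference
genomes.  The classifier consumes standard 12-column tabular alignment
files (blastn ``-outfmt 6``), one per organelle reference, and applies:

* chloroplast: e-value <= 1e-5, identity >= 95 %, coverage >= 80 %
* mitochondrion: e-value <= 1e-5, identity >= 80 %, coverage >= 50 %
* only scaffolds longer than 200 bp (the sequencing library length) are
  eligible for an organelle call
* everything else is nuclear by exclusion

Coverage is the alignment span over the scaffold (query) length.
Chloroplast takes precedence when both organelles match; conflicts are
recorded.  Also provides the shared/organ-specific set decomposition
(Venn regions and shared fraction) used to compare genome usage between
organs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .counts import ValidationError

__all__ = [
    "OUTFMT6_COLUMNS",
    "read_hits",
    "OrganelleThresholds",
    "CHLOROPLAST_THRESHOLDS",
    "MITOCHONDRION_THRESHOLDS",
    "PartitionResult",
    "classify_scaffolds",
    "class_summary",
    "shared_sets",
    "SharedSets",
]

OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

CHLOROPLAST = "chloroplast"
MITOCHONDRION = "mitochondrion"
NUCLEUS = "nucleus"

MIN_SCAFFOLD_LEN = 200  # nt; sequencing library length gate


def read_hits(path) -> pd.DataFrame:
    """Parse a 12-column tabular alignment file (``-outfmt 6``).

    Malformed rows raise ``ValidationError`` with the 1-based line number.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=OUTFMT6_COLUMNS,
                         comment="#")
    except pd.errors.ParserError as exc:
        raise ValidationError(f"malformed hit file {path}: {exc}") from exc
    for col in ("pident", "length", "evalue", "bitscore"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            line = int(np.flatnonzero(bad)[0]) + 1
            raise ValidationError(
                f"malformed hit row at line {line} of {path}: "
                f"non-numeric {col!r}"
            )
        df[col] = pd.to_numeric(df[col])
    if (df["pident"] < 0).any() or (df["pident"] > 100).any():
        line = int(np.flatnonzero((df.pident < 0) | (df.pident > 100))[0]) + 1
        raise ValidationError(f"identity outside [0, 100] at line {line}")
    if (df["length"] <= 0).any():
        line = int(np.flatnonzero(df["length"] <= 0)[0]) + 1
        raise ValidationError(f"non-positive alignment length at line {line}")
    if (df["evalue"] < 0).any():
        line = int(np.flatnonzero(df["evalue"] < 0)[0]) + 1
        raise ValidationError(f"negative e-value at line {line}")
    df["qseqid"] = df["qseqid"].astype(str)
    df["sseqid"] = df["sseqid"].astype(str)
    return df


@dataclass(frozen=True)
class OrganelleThresholds:
    """Alignment acceptance thresholds for one organelle reference."""

    max_evalue: float
    min_identity: float   # percent
    min_coverage: float   # percent of scaffold length


CHLOROPLAST_THRESHOLDS = OrganelleThresholds(1e-5, 95.0, 80.0)
MITOCHONDRION_THRESHOLDS = OrganelleThresholds(1e-5, 80.0, 50.0)


@dataclass
class PartitionResult:
    """Disjoint scaffold → {chloroplast, mitochondrion, nucleus} cover."""

    classes: pd.Series            # scaffold -> class label
    classifying_hits: pd.DataFrame  # best passing hit per organelle scaffold
    conflicts: pd.DataFrame       # scaffolds passing both organelle filters

    def class_counts(self) -> pd.Series:
        return self.classes.value_counts().reindex(
            [CHLOROPLAST, MITOCHONDRION, NUCLEUS], fill_value=0)

    def members(self, label: str) -> pd.Index:
        return self.classes.index[self.classes == label]


def _passing(hits: pd.DataFrame, lengths: pd.Series,
             thr: OrganelleThresholds) -> pd.DataFrame:
    cov = hits["length"] / hits["qseqid"].map(lengths).to_numpy() * 100.0
    ok = (hits["evalue"] <= thr.max_evalue) \
        & (hits["pident"] >= thr.min_identity) \
        & (cov >= thr.min_coverage)
    out = hits.loc[ok].copy()
    out["coverage"] = cov[ok]
    return out


def _best_per_query(passing: pd.DataFrame) -> pd.DataFrame:
    # best passing hit: lowest e-value, then highest bitscore
    ordered = passing.sort_values(["evalue", "bitscore"],
                                  ascending=[True, False], kind="stable")
    return ordered.drop_duplicates("qseqid", keep="first")


def classify_scaffolds(hits_cp: pd.DataFrame, hits_mt: pd.DataFrame,
                       lengths: pd.Series,
                       min_len: int = MIN_SCAFFOLD_LEN,
                       cp_thresholds: OrganelleThresholds = CHLOROPLAST_THRESHOLDS,
                       mt_thresholds: OrganelleThresholds = MITOCHONDRION_THRESHOLDS,
                       ) -> PartitionResult:
    """Assign every scaffold to exactly one subcellular class.

    A scaffold longer than ``min_len`` is chloroplast if any chloroplast
    hit passes the chloroplast thresholds; otherwise mitochondrial if any
    mitochondrial hit passes; otherwise nuclear.  Scaffolds at or below
    ``min_len`` are nuclear regardless of hits.  Hits naming unknown
    scaffolds are an error.
    """
    known = set(lengths.index.astype(str))
    for name, hits in (("chloroplast", hits_cp), ("mitochondrion", hits_mt)):
        unknown = sorted(set(hits["qseqid"]) - known)
        if unknown:
            raise ValidationError(
                f"{name} hits reference unknown scaffolds: {unknown[:10]}"
            )

    eligible = lengths.index[lengths > min_len]
    cp_pass = _best_per_query(_passing(
        hits_cp[hits_cp["qseqid"].isin(eligible)], lengths, cp_thresholds))
    mt_pass = _best_per_query(_passing(
        hits_mt[hits_mt["qseqid"].isin(eligible)], lengths, mt_thresholds))

    cp_set = set(cp_pass["qseqid"])
    mt_set = set(mt_pass["qseqid"])
    conflicts = cp_pass[cp_pass["qseqid"].isin(mt_set)].assign(
        also=MITOCHONDRION)

    classes = pd.Series(NUCLEUS, index=lengths.index, name="class")
    classes.loc[classes.index.isin(mt_set)] = MITOCHONDRION
    classes.loc[classes.index.isin(cp_set)] = CHLOROPLAST  # precedence

    parts = [
        cp_pass.assign(organelle=CHLOROPLAST),
        mt_pass[~mt_pass["qseqid"].isin(cp_set)].assign(
            organelle=MITOCHONDRION),
    ]
    parts = [p for p in parts if len(p)]
    best = pd.concat(parts, ignore_index=True) if parts else \
        pd.DataFrame(columns=OUTFMT6_COLUMNS + ["coverage", "organelle"])
    return PartitionResult(classes=classes, classifying_hits=best,
                           conflicts=conflicts)


def class_summary(partition: PartitionResult,
                  expression: pd.DataFrame) -> pd.DataFrame:
    """Per-class per-sample scaffold counts and summed expression.

    ``expression`` is any scaffold × sample matrix (cleaned counts or
    normalized levels); a scaffold counts as present in a sample when its
    value is non-zero.
    """
    rows = []
    for label in (CHLOROPLAST, MITOCHONDRION, NUCLEUS):
        members = partition.members(label)
        sub = expression.reindex(members).fillna(0.0)
        for sample in expression.columns:
            col = sub[sample]
            rows.append({
                "class": label,
                "sample": sample,
                "n_scaffolds": int((col != 0).sum()),
                "total_expression": float(col.sum()),
            })
    return pd.DataFrame(rows)


@dataclass
class SharedSets:
    """Venn-region decomposition of per-group expressed scaffold sets."""

    regions: dict[frozenset, int]   # group-name combination -> exclusive count
    shared_count: int               # expressed in every group
    union_size: int                 # expressed in at least one group
    shared_fraction: float          # shared_count / union_size

    def to_json_dict(self) -> dict:
        return {
            "regions": {"&".join(sorted(k)): v for k, v in self.regions.items()},
            "shared_count": self.shared_count,
            "union_size": self.union_size,
            "shared_fraction": self.shared_fraction,
        }


def shared_sets(expressed: dict[str, set]) -> SharedSets:
    """Exclusive Venn-region counts and the all-groups shared fraction.

    ``expressed`` maps group name → set of scaffolds with non-zero
    cleaned counts in that group.  Requires at least two groups and a
    non-empty union.
    """
    if len(expressed) < 2:
        raise ValidationError("need at least 2 groups")
    names = list(expressed)
    union: set = set().union(*expressed.values())
    if not union:
        raise ValidationError("union of expressed sets is empty")
    regions: dict[frozenset, int] = {}
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            inside = set.intersection(*(expressed[n] for n in combo))
            outside = set().union(
                *(expressed[n] for n in names if n not in combo)) \
                if len(combo) < len(names) else set()
            regions[frozenset(combo)] = len(inside - outside)
    shared = len(set.intersection(*expressed.values()))
    return SharedSets(
        regions=regions,
        shared_count=shared,
        union_size=len(union),
        shared_fraction=shared / len(union),
    )
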