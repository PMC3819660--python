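"""Count-matrix handling and scaffold abundance estimation.

The unit of quantification is the *scaffold*: an assembled transcript
sequence from de novo short-read assembly.  Raw input is a table of
paired-end read counts per scaffold per sample together with scaffold
lengths.  Two operations turn this into abundances:

* :func:`clean_counts` — read counts below two are treated as fortuitous
  mapping artefacts and zeroed.
* :func:`estimate_abundance` — the abundance of scaffold *g* in sample *k*
  is ``Y_gk = count_gk / (length_g * total_k)``, i.e. the read count
  divided by the scaffold length and the sample's total read count.

Per-sample totals are always the column sums of the *cleaned* counts, so
the toolkit is self-contained: it never needs the unassembled raw yield.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "CountMatrix",
    "AbundanceMatrix",
    "clean_counts",
    "estimate_abundance",
    "read_counts_tsv",
    "read_lengths",
]

LOW_READ_THRESHOLD = 2  # counts below this are zeroed as fortuitous


class ValidationError(ValueError):
    """Raised when an input table violates its invariants."""


@dataclass
class CountMatrix:
    """Raw paired-end read counts per scaffold per sample, with lengths.

    Parameters
    ----------
    counts : pandas.DataFrame
        Non-negative integer matrix, index = scaffold IDs, columns =
        sample IDs.
    lengths : pandas.Series
        Positive scaffold length in nucleotides, indexed by scaffold ID.
        Must cover every scaffold in ``counts``.
    """

    counts: pd.DataFrame
    lengths: pd.Series

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            dup = c.index[c.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate scaffold IDs: {dup}")
        if c.columns.has_duplicates:
            dup = c.columns[c.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample IDs: {dup}")
        vals = c.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if np.any(vals < 0):
            bad = c.index[(vals < 0).any(axis=1)].tolist()
            raise ValidationError(f"negative counts for scaffolds: {bad}")
        if np.any(vals != np.floor(vals)):
            raise ValidationError("counts must be integers")
        missing = c.index.difference(self.lengths.index)
        if len(missing) > 0:
            raise ValidationError(
                f"missing length for scaffolds: {missing.tolist()}"
            )
        self.lengths = self.lengths.reindex(c.index)
        if np.any(self.lengths.to_numpy() <= 0):
            bad = self.lengths.index[self.lengths <= 0].tolist()
            raise ValidationError(f"non-positive length for scaffolds: {bad}")

    @property
    def scaffold_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns


@dataclass
class AbundanceMatrix:
    """Length- and depth-scaled abundances ``Y_gk`` with totals ``N_k``.

    ``Y`` is the scaffold × sample abundance matrix; ``N`` holds the
    per-sample totals ``N_k = sum_g Y_gk``.
    """

    Y: pd.DataFrame
    N: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.N is None:
            self.N = self.Y.sum(axis=0)
        if np.any(self.Y.to_numpy() < 0):
            raise ValidationError("abundances must be non-negative")
        if not np.allclose(self.N.to_numpy(), self.Y.sum(axis=0).to_numpy(),
                           rtol=1e-9, atol=0.0):
            raise ValidationError("N_k must equal the column sums of Y")

    @property
    def scaffold_ids(self) -> pd.Index:
        return self.Y.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.Y.columns


def clean_counts(raw: CountMatrix) -> CountMatrix:
    """Zero out entries below the low-read threshold.

    A read count of 0 or 1 is considered a fortuitous mapping and set to
    zero; counts of two or more pass through unchanged.  Idempotent.
    """
    cleaned = raw.counts.where(raw.counts >= LOW_READ_THRESHOLD, 0)
    return CountMatrix(counts=cleaned, lengths=raw.lengths)


def estimate_abundance(clean: CountMatrix) -> AbundanceMatrix:
    """Compute ``Y_gk = count_gk / (length_g * total_k)``.

    ``total_k`` is the column sum of the cleaned counts.  A sample whose
    total is zero has undefined abundance and raises ``ValidationError``.
    """
    totals = clean.counts.sum(axis=0)
    dead = totals.index[totals == 0].tolist()
    if dead:
        raise ValidationError(
            f"total count is zero for samples {dead}; abundance undefined"
        )
    Y = clean.counts.div(clean.lengths, axis=0).div(totals, axis=1)
    return AbundanceMatrix(Y=Y.astype(float))


# ---------------------------------------------------------------------------
# readers

def read_counts_tsv(path) -> pd.DataFrame:
    """Read a counts TSV: header row of sample IDs, first column scaffold ID."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def read_lengths(path, fmt: str | None = None) -> pd.Series:
    """Read scaffold lengths from a FASTA file or a 2-column TSV.

    ``fmt`` may be ``"fasta"`` or ``"tsv"``; when omitted it is inferred
    from the file suffix (``.fa``/``.fasta`` → FASTA, else TSV).
    """
    path = str(path)
    if fmt is None:
        fmt = "fasta" if path.endswith((".fa", ".fasta", ".fna")) else "tsv"
    if fmt == "fasta":
        lengths = {rec.id: len(rec.seq) for rec in SeqIO.parse(path, "fasta")}
        return pd.Series(lengths, name="length", dtype=int)
    df = pd.read_csv(path, sep="\t", header=None, names=["scaffold", "length"])
    s = pd.Series(df["length"].to_numpy(), index=df["scaffold"].astype(str))
    return s.astype(int)


def build_count_matrix(counts: pd.DataFrame, lengths: pd.Series,
                       allow_missing: bool = False) -> CountMatrix:
    """Assemble a validated :class:`CountMatrix` from its two tables.

    Scaffolds present in ``counts`` but absent from ``lengths`` are an
    error unless ``allow_missing`` is set, in which case the offending
    rows are dropped with a warning.
    """
    missing = counts.index.difference(lengths.index)
    if len(missing) > 0 and allow_missing:
        warnings.warn(
            f"dropping {len(missing)} scaffolds without lengths: "
            f"{missing.tolist()[:10]}{'...' if len(missing) > 10 else ''}"
        )
        counts = counts.drop(index=missing)
    return CountMatrix(counts=counts, lengths=lengths)
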