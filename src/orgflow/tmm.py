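"""n-sample trimmed-mean (TMM-style) normalization against a synthetic reference.

Library-size scaling alone does not make de novo transcriptome samples
comparable: an organ that strongly expresses a private set of transcripts
depresses the relative abundance of every shared transcript.  The remedy
implemented here estimates a per-sample scaling factor from the genes the
samples have in common, after trimming the genes with extreme ratios.

Procedure for n samples:

1. *Reference profile.*  G = scaffolds with non-zero abundance in every
   sample; the virtual reference abundance is the arithmetic mean
   ``Y_g = sum_k Y_gk / n`` with total ``N = sum_{g in G} Y_g``.
2. *M/A statistics* per sample k, over G only::

       M_g = log2( (Y_gk / N_k) / (Y_g / N) )
       A_g = 0.5 * log2( (Y_gk / N_k) * (Y_g / N) )

   with weights ``w_g = 1/Y_gk + 1/Y_g`` (approximate inverse-variance
   form; the exact binomial form is available via ``exact_weights``).
3. *Trimming.*  M and A are min-max normalized per sample and genes are
   kept only when both fall strictly inside (M_lower, M_upper) and
   (A_lower, A_upper); defaults (0.3, 0.7) and (0.2, 0.8).  The kept
   genes form G*.
4. *Factor.*  ``log2 TMM_k = sum_{g in G*} w_g M_g / sum w_g`` and
   ``R_k = 2**log2 TMM_k``.

Normalized expression is reported as ``(Y_gk / N_k) / R_k * 1e6`` — a
per-million convention; the constant cancels in every ratio, fold change
and correlation downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .counts import AbundanceMatrix, CountMatrix, ValidationError

__all__ = [
    "TrimBounds",
    "ReferenceProfile",
    "MAStatistics",
    "NormalizationResult",
    "TMMNormalization",
    "TMMResults",
    "build_reference",
    "compute_ma",
    "trim_genes",
    "normalization_factor",
    "normalize",
]

NORMALIZED_SCALE = 1e6  # per-million reporting convention


@dataclass(frozen=True)
class TrimBounds:
    """Min-max trimming windows for M and A, each in [0, 1]."""

    m_lower: float = 0.3
    m_upper: float = 0.7
    a_lower: float = 0.2
    a_upper: float = 0.8

    def __post_init__(self) -> None:
        for name in ("m_lower", "m_upper", "a_lower", "a_upper"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not self.m_lower < self.m_upper:
            raise ValueError("require m_lower < m_upper")
        if not self.a_lower < self.a_upper:
            raise ValueError("require a_lower < a_upper")


@dataclass
class ReferenceProfile:
    """The common gene set G and its mean-abundance virtual sample."""

    genes: pd.Index          # G: expressed (Y_gk != 0) in all samples
    y_ref: pd.Series         # Y_g = mean_k Y_gk over G
    n_ref: float             # N = sum of y_ref
    n_samples: int


@dataclass
class MAStatistics:
    """Per-sample M, A and weight vectors over G, with their extremes."""

    sample: str
    m: pd.Series
    a: pd.Series
    w: pd.Series

    @property
    def m_min(self) -> float:
        return float(self.m.min())

    @property
    def m_max(self) -> float:
        return float(self.m.max())

    @property
    def a_min(self) -> float:
        return float(self.a.min())

    @property
    def a_max(self) -> float:
        return float(self.a.max())


@dataclass
class SampleFactor:
    """Trimmed set and normalization factor for one sample."""

    sample: str
    g_star: pd.Index
    log_tmm: float
    r: float
    stats: MAStatistics


@dataclass
class NormalizationResult:
    """All per-sample factors plus the reference profile used."""

    reference: ReferenceProfile
    bounds: TrimBounds
    per_sample: dict[str, SampleFactor]

    @property
    def factors(self) -> pd.Series:
        return pd.Series({k: sf.r for k, sf in self.per_sample.items()},
                         name="R")

    def factor_table(self) -> pd.DataFrame:
        rows = []
        for k, sf in self.per_sample.items():
            rows.append({
                "sample": k,
                "n_common": len(self.reference.genes),
                "n_trimmed": len(sf.g_star),
                "log2_tmm": sf.log_tmm,
                "R": sf.r,
            })
        return pd.DataFrame(rows).set_index("sample")

    def audit(self) -> dict:
        """JSON-serializable record of bounds and per-sample extremes."""
        return {
            "bounds": {
                "m_lower": self.bounds.m_lower,
                "m_upper": self.bounds.m_upper,
                "a_lower": self.bounds.a_lower,
                "a_upper": self.bounds.a_upper,
            },
            "n_common_genes": int(len(self.reference.genes)),
            "samples": {
                k: {
                    "m_min": sf.stats.m_min, "m_max": sf.stats.m_max,
                    "a_min": sf.stats.a_min, "a_max": sf.stats.a_max,
                    "n_trimmed": int(len(sf.g_star)),
                    "log2_tmm": sf.log_tmm, "R": sf.r,
                }
                for k, sf in self.per_sample.items()
            },
        }


def build_reference(ab: AbundanceMatrix) -> ReferenceProfile:
    """Mean-abundance reference over genes expressed in every sample."""
    if ab.Y.shape[1] < 2:
        raise ValidationError("need at least 2 samples to normalize")
    mask = (ab.Y != 0).all(axis=1)
    genes = ab.Y.index[mask]
    if len(genes) == 0:
        raise ValidationError("no commonly expressed genes")
    y_ref = ab.Y.loc[genes].mean(axis=1)
    return ReferenceProfile(
        genes=genes,
        y_ref=y_ref,
        n_ref=float(y_ref.sum()),
        n_samples=ab.Y.shape[1],
    )


def compute_ma(ab: AbundanceMatrix, ref: ReferenceProfile, sample: str,
               exact_weights: bool = False) -> MAStatistics:
    """M, A and weights for one sample against the reference profile."""
    y_k = ab.Y.loc[ref.genes, sample]
    n_k = float(ab.N[sample])
    if (y_k <= 0).any():
        bad = y_k.index[y_k <= 0].tolist()
        raise ValidationError(
            f"non-positive abundance inside G for sample {sample}: {bad[:5]}"
        )
    rel_k = y_k / n_k
    rel_ref = ref.y_ref / ref.n_ref
    m = np.log2(rel_k / rel_ref)
    a = 0.5 * np.log2(rel_k * rel_ref)
    if exact_weights:
        w = (n_k - y_k) / (n_k * y_k) \
            + (ref.n_ref - ref.y_ref) / (ref.n_ref * ref.y_ref)
    else:
        w = 1.0 / y_k + 1.0 / ref.y_ref
    return MAStatistics(sample=sample, m=m, a=a, w=w)


def trim_genes(stats: MAStatistics, bounds: TrimBounds,
               mode: str = "minmax") -> pd.Index:
    """Keep genes strictly inside both trimming windows.

    ``mode="minmax"`` (default) rescales M and A by their extremes, so a
    gene is kept when its min-max-normalized position lies strictly
    inside the window; single extreme genes define the range.
    ``mode="quantile"`` trims by rank quantile instead (the classical
    trimmed-mean scheme), discarding a fixed fraction of genes at each
    end regardless of how extreme they are.

    When all M (or all A) values coincide that criterion carries no
    information, so it passes every gene.
    """
    if mode not in ("minmax", "quantile"):
        raise ValueError("mode must be 'minmax' or 'quantile'")

    def _inside(v: pd.Series, lo: float, hi: float) -> np.ndarray:
        span = float(v.max() - v.min())
        if span == 0.0:
            return np.ones(len(v), dtype=bool)
        if mode == "minmax":
            q = ((v - v.min()) / span).to_numpy()
        else:
            q = (rankdata(v.to_numpy()) - 0.5) / len(v)
        return (lo < q) & (q < hi)

    keep = _inside(stats.m, bounds.m_lower, bounds.m_upper) \
        & _inside(stats.a, bounds.a_lower, bounds.a_upper)
    g_star = stats.m.index[keep]
    if len(g_star) == 0:
        raise ValidationError(
            f"trimming left no genes for sample {stats.sample}; "
            "widen the trim bounds"
        )
    return g_star


def normalization_factor(stats: MAStatistics,
                         g_star: pd.Index) -> tuple[float, float]:
    """Weighted mean of M over G*; returns ``(log2_tmm, R)``."""
    if len(g_star) == 0:
        raise ValidationError("empty trimmed set")
    w = stats.w.loc[g_star]
    total = float(w.sum())
    if total == 0.0:
        raise ValidationError("total weight is zero")
    log_tmm = float((w * stats.m.loc[g_star]).sum() / total)
    return log_tmm, float(2.0 ** log_tmm)


def normalize(ab: AbundanceMatrix, bounds: TrimBounds = TrimBounds(),
              exact_weights: bool = False, trim_mode: str = "minmax"
              ) -> tuple[NormalizationResult, pd.DataFrame]:
    """Full pipeline: reference, per-sample M/A, trimming, factors.

    Returns the result object (with every intermediate for audit) and the
    normalized matrix ``(Y_gk / N_k) / R_k * 1e6``.
    """
    ref = build_reference(ab)
    per_sample: dict[str, SampleFactor] = {}
    for k in ab.sample_ids:
        try:
            stats = compute_ma(ab, ref, k, exact_weights=exact_weights)
            g_star = trim_genes(stats, bounds, mode=trim_mode)
            log_tmm, r = normalization_factor(stats, g_star)
        except ValidationError as exc:
            raise ValidationError(f"sample {k}: {exc}") from exc
        per_sample[k] = SampleFactor(sample=k, g_star=g_star,
                                     log_tmm=log_tmm, r=r, stats=stats)
    result = NormalizationResult(reference=ref, bounds=bounds,
                                 per_sample=per_sample)
    rel = ab.Y.div(ab.N, axis=1)
    normalized = rel.div(result.factors, axis=1) * NORMALIZED_SCALE
    return result, normalized


# ---------------------------------------------------------------------------
# model-style front end

class TMMNormalization:
    """Trimmed-mean normalization model over a multi-sample count table.

    Construct from an :class:`~orgflow.counts.AbundanceMatrix`, or from a
    raw count matrix via :meth:`from_counts` (which applies the low-read
    zeroing rule first).  :meth:`fit` estimates one factor per sample and
    returns a :class:`TMMResults`.

    Examples
    --------
    >>> model = TMMNormalization.from_counts(cm)        # doctest: +SKIP
    >>> res = model.fit()                               # doctest: +SKIP
    >>> print(res.summary())                            # doctest: +SKIP
    """

    def __init__(self, abundance: AbundanceMatrix,
                 bounds: TrimBounds = TrimBounds(),
                 exact_weights: bool = False,
                 trim_mode: str = "minmax") -> None:
        self.abundance = abundance
        self.bounds = bounds
        self.exact_weights = exact_weights
        self.trim_mode = trim_mode

    @classmethod
    def from_counts(cls, cm: CountMatrix, **kwargs) -> "TMMNormalization":
        from .counts import clean_counts, estimate_abundance
        return cls(estimate_abundance(clean_counts(cm)), **kwargs)

    def fit(self) -> "TMMResults":
        result, normalized = normalize(self.abundance, self.bounds,
                                       self.exact_weights, self.trim_mode)
        return TMMResults(self, result, normalized)


class TMMResults:
    """Fitted factors, intermediates and the normalized matrix."""

    def __init__(self, model: TMMNormalization, result: NormalizationResult,
                 normalized: pd.DataFrame) -> None:
        self.model = model
        self.result = result
        self.normalized = normalized

    @property
    def factors(self) -> pd.Series:
        return self.result.factors

    @property
    def reference(self) -> ReferenceProfile:
        return self.result.reference

    def factor_table(self) -> pd.DataFrame:
        return self.result.factor_table()

    def audit(self) -> dict:
        return self.result.audit()

    def summary(self) -> str:
        b = self.result.bounds
        tbl = self.factor_table()
        lines = [
            "Trimmed-mean normalization (n-sample, synthetic reference)",
            "=" * 58,
            f"samples: {len(tbl)}    common genes |G|: "
            f"{len(self.reference.genes)}",
            f"trim windows: M ({b.m_lower}, {b.m_upper})   "
            f"A ({b.a_lower}, {b.a_upper})",
            f"weights: {'exact' if self.model.exact_weights else 'approximate'}",
            "-" * 58,
            tbl.to_string(float_format=lambda x: f"{x:.6g}"),
            "=" * 58,
        ]
        return "\n".join(lines)
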