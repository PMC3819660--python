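"""Seeded synthetic inputs with known ground truth for every module.

The generator emulates the structure of a multi-organ de novo
transcriptome experiment: a shared majority of well-measured
transcripts, a minority up-regulated in chosen samples (composition
bias), unequal sequencing depths, organelle-derived scaffolds planted
with alignment hits inside the classification thresholds, and a small
pathway whose nodes carry planted fold changes.

Modelling choices (see docs/methods.md for the full rationale):

* Counts are negative-binomial around length- and depth-scaled means.
  The emulated design has no biological replicates — each sample is one
  library from one organ — so the noise is technical and near-Poisson;
  the default dispersion is 0.01.
* Per-gene expression rates follow a shifted lognormal, so every
  commonly expressed gene sits well above the detection floor.  Absence
  of expression is modelled by the dropout path and by organ-specific
  transcripts, not by genes hovering at one or two reads.
* Pathway fold changes are planted as organ-specific isoform switching:
  each node has a shared isoform expressed everywhere plus a
  target-only isoform sized to produce the planted node-level fold.
  Large fold changes therefore come from transcripts absent in the
  reference organ — as organ-specific genes do — rather than from
  extreme ratios inside the commonly expressed set.

Everything is reproducible bit-for-bit from ``SimulationSpec.seed``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .counts import ValidationError

__all__ = [
    "SimulationSpec",
    "GroundTruth",
    "SimulatedData",
    "simulate",
    "boundary_partition_fixture",
]

# toy glycolysis: EC-labelled nodes in reaction order
_PATHWAY_NODES = [
    ("hk", "EC2.7.1.1"), ("pgi", "EC5.3.1.9"), ("pfk", "EC2.7.1.11"),
    ("ald", "EC4.1.2.13"), ("pk", "EC2.7.1.40"),
]
_PATHWAY_EDGES = [
    ("hk", "pgi", "G6P"), ("pgi", "pfk", "F6P"),
    ("pfk", "ald", "F1,6BP"), ("ald", "pk", "PEP"),
]
# node-level target/reference folds, placed well inside the tier intervals
_PATHWAY_FOLDS = (1.2, 4.0, 15.0, 150.0, math.inf)


@dataclass
class SimulationSpec:
    """Study-design parameters for the synthetic experiment.

    Defaults describe the reference condition used throughout: 2000
    genes, 3 samples (deep bulk libraries at 2e7, 1e7 and 4e7 reads),
    5 % of genes 8-fold up-regulated in the last sample, near-Poisson
    technical noise, scaffold lengths 200-3000 nt, no dropout.
    """

    n_genes: int = 2000
    n_samples: int = 3
    seed: int = 0
    library_sizes: list[float] = field(default_factory=list)
    de_fraction: float = 0.05
    de_fold: float = 8.0
    de_samples: list[int] = field(default_factory=list)  # indices; default: last
    length_min: int = 200
    length_max: int = 3000
    dispersion: float = 0.01
    rate_sigma: float = 1.5      # lognormal sigma of expression rates
    rate_floor: float = 0.15     # shift keeping common genes well-measured
    cp_fraction: float = 0.05
    mt_fraction: float = 0.02
    dropout: float = 0.0
    plant_pathway: bool = True

    def __post_init__(self) -> None:
        if not self.library_sizes:
            base = [2e7, 1e7, 4e7]
            self.library_sizes = [base[i % 3] for i in range(self.n_samples)]
        if len(self.library_sizes) != self.n_samples:
            raise ValidationError("library_sizes length must equal n_samples")
        if not self.de_samples:
            self.de_samples = [self.n_samples - 1]
        for frac_name in ("de_fraction", "cp_fraction", "mt_fraction",
                          "dropout"):
            v = getattr(self, frac_name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{frac_name}={v} outside [0, 1]")
        if self.cp_fraction + self.mt_fraction > 1.0:
            raise ValidationError("organelle fractions exceed 1")
        if self.n_genes < 1 or self.n_samples < 2:
            raise ValidationError("need n_genes >= 1 and n_samples >= 2")
        if self.de_fold <= 0 or self.dispersion < 0:
            raise ValidationError("de_fold must be > 0 and dispersion >= 0")
        if not 0 < self.length_min <= self.length_max:
            raise ValidationError("invalid length range")
        if any(k < 0 or k >= self.n_samples for k in self.de_samples):
            raise ValidationError("de_samples index out of range")

    @classmethod
    def from_yaml(cls, path) -> "SimulationSpec":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)


@dataclass
class GroundTruth:
    """The planted design facts the pipeline should recover."""

    true_factors: pd.Series          # per sample, vs the mean-profile reference
    classes: pd.Series               # scaffold -> subcellular class
    de_genes: list[str]
    pathway_tiers: dict[str, int]
    pathway_directions: dict[str, str]


@dataclass
class SimulatedData:
    """All generated input tables plus the ground truth."""

    counts: pd.DataFrame
    lengths: pd.Series
    hits_cp: pd.DataFrame
    hits_mt: pd.DataFrame
    pathway_nodes: pd.DataFrame
    pathway_edges: pd.DataFrame
    target_samples: list[str]
    ref_samples: list[str]
    truth: GroundTruth

    def write(self, out_dir) -> dict[str, Path]:
        """Write every table as TSV (plus truth as JSON); returns paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        paths["counts"] = out / "counts.tsv"
        self.counts.to_csv(paths["counts"], sep="\t", index_label="scaffold")
        paths["lengths"] = out / "lengths.tsv"
        self.lengths.to_frame("length").to_csv(paths["lengths"], sep="\t",
                                               header=False)
        paths["hits_cp"] = out / "hits_chloroplast.tsv"
        self.hits_cp.to_csv(paths["hits_cp"], sep="\t", index=False,
                            header=False)
        paths["hits_mt"] = out / "hits_mitochondrion.tsv"
        self.hits_mt.to_csv(paths["hits_mt"], sep="\t", index=False,
                            header=False)
        paths["pathway_nodes"] = out / "pathway_nodes.tsv"
        self.pathway_nodes.to_csv(paths["pathway_nodes"], sep="\t",
                                  index=False)
        paths["pathway_edges"] = out / "pathway_edges.tsv"
        self.pathway_edges.to_csv(paths["pathway_edges"], sep="\t",
                                  index=False)
        paths["truth"] = out / "truth.json"
        truth = {
            "true_factors": self.truth.true_factors.to_dict(),
            "classes": self.truth.classes.to_dict(),
            "de_genes": self.truth.de_genes,
            "pathway_tiers": self.truth.pathway_tiers,
            "pathway_directions": self.truth.pathway_directions,
            "target_samples": self.target_samples,
            "ref_samples": self.ref_samples,
        }
        paths["truth"].write_text(json.dumps(truth, indent=1))
        return paths


def _true_factors(mu: np.ndarray, lengths: np.ndarray,
                  plain: np.ndarray, samples: list[str]) -> pd.Series:
    """Closed-form factors implied by the noise-free planted design.

    For a plain (non-differential, non-planted) gene the ratio of its
    relative abundance in sample k to that in the mean-profile reference
    is the same for every such gene; that common ratio is the factor a
    trimmed-mean estimator targets.  Computed directly from the expected
    abundances — no trimming or weighting involved.
    """
    totals = mu.sum(axis=0)
    Y0 = mu / lengths[:, None] / totals[None, :]
    in_g = (Y0 > 0).all(axis=1)
    y_ref = Y0[in_g].mean(axis=1)
    n_ref = y_ref.sum()
    # sample-side relative abundance uses the full per-sample total;
    # the reference profile exists only on the common set
    rel = Y0[in_g] / Y0.sum(axis=0, keepdims=True)
    rel_ref = y_ref / n_ref
    use = plain[in_g]
    ratios = rel[use, :] / rel_ref[use, None]
    return pd.Series(np.median(ratios, axis=0), index=samples, name="R_true")


def simulate(spec: SimulationSpec) -> SimulatedData:
    """Generate the full synthetic input set for one seeded design."""
    rng = np.random.default_rng(spec.seed)
    n_g, n_s = spec.n_genes, spec.n_samples
    scaffolds = [f"SCF{i + 1:06d}" for i in range(n_g)]
    samples = [f"S{i + 1}" for i in range(n_s)]

    lengths = rng.integers(spec.length_min, spec.length_max + 1, size=n_g)
    rates = spec.rate_floor + rng.lognormal(mean=0.0, sigma=spec.rate_sigma,
                                            size=n_g)

    # per-gene per-sample rate multipliers start at 1 (no signal)
    phi = np.ones((n_g, n_s))

    # differential-expression plan: asymmetric up-regulation
    n_de = int(round(spec.de_fraction * n_g))
    de_idx = rng.choice(n_g, size=n_de, replace=False) if n_de else \
        np.empty(0, dtype=int)
    for k in spec.de_samples:
        phi[de_idx, k] = spec.de_fold

    plain = np.ones(n_g, dtype=bool)   # genes carrying no planted signal
    plain[de_idx] = False

    # pathway planting: shared + target-only isoform per node
    ref_idx = [n_s - 1]
    target_idx = [i for i in range(n_s) if i not in ref_idx]
    pathway_tiers: dict[str, int] = {}
    pathway_dirs: dict[str, str] = {}
    node_scaffolds: dict[str, list[str]] = {}
    if spec.plant_pathway:
        candidates = np.flatnonzero(plain)
        n_needed = 2 * len(_PATHWAY_NODES)
        chosen = rng.choice(candidates, size=n_needed, replace=False)
        shared_idx, specific_idx = chosen[::2], chosen[1::2]
        for (node, _label), gs, gt, f in zip(_PATHWAY_NODES, shared_idx,
                                             specific_idx, _PATHWAY_FOLDS):
            if math.isinf(f):
                # node carried by a target-only transcript
                rates[gt] = rates[gs]
                phi[gt, :] = 0.0
                phi[gt, target_idx] = 1.0
                node_scaffolds[node] = [scaffolds[gt]]
                plain[gt] = False
                pathway_tiers[node], pathway_dirs[node] = 3, "target_up"
                continue
            # shared isoform stays at fold 1; specific isoform carries f-1
            rates[gt] = rates[gs] * max(f - 1.0, 0.0)
            phi[gt, :] = 0.0
            if f > 1.0:
                phi[gt, target_idx] = 1.0
            node_scaffolds[node] = [scaffolds[gs], scaffolds[gt]]
            plain[[gs, gt]] = False
            tier = sum(f > t for t in (2.0, 10.0, 100.0))
            pathway_tiers[node] = tier
            pathway_dirs[node] = "target_up" if tier else "approx"

    q = rates[:, None] * lengths[:, None] * phi
    share = q / q.sum(axis=0, keepdims=True)
    mu = share * np.asarray(spec.library_sizes)[None, :]

    if spec.dispersion > 0:
        r_nb = 1.0 / spec.dispersion
        p_nb = r_nb / (r_nb + mu)
        counts = np.where(mu > 0,
                          rng.negative_binomial(r_nb,
                                                np.clip(p_nb, 1e-12, 1.0)),
                          0)
    else:
        counts = rng.poisson(mu)
    if spec.dropout > 0:
        drop = rng.random(counts.shape) < spec.dropout
        counts = np.where(drop, 0, counts)

    true_factors = _true_factors(mu, lengths.astype(float), plain, samples)

    # subcellular classes with planted alignment hits inside the thresholds
    classes = pd.Series("nucleus", index=pd.Index(scaffolds, name="scaffold"))
    eligible = np.flatnonzero(lengths > 200)
    n_cp = int(round(spec.cp_fraction * n_g))
    n_mt = int(round(spec.mt_fraction * n_g))
    organelle_idx = rng.choice(eligible, size=min(n_cp + n_mt, len(eligible)),
                               replace=False)
    cp_idx, mt_idx = organelle_idx[:n_cp], organelle_idx[n_cp:]
    classes.iloc[cp_idx] = "chloroplast"
    classes.iloc[mt_idx] = "mitochondrion"

    def _plant_hits(idx: np.ndarray, subject: str, ident_rng: tuple,
                    cov_rng: tuple) -> pd.DataFrame:
        rows = []
        for g in idx:
            ident = rng.uniform(*ident_rng)
            cov = rng.uniform(*cov_rng)
            aln = min(int(np.ceil(cov / 100.0 * lengths[g])), int(lengths[g]))
            rows.append({
                "qseqid": scaffolds[g], "sseqid": subject,
                "pident": round(ident, 2), "length": aln,
                "mismatch": int((100 - ident) / 100 * aln),
                "gapopen": 0, "qstart": 1, "qend": aln,
                "sstart": 1, "send": aln,
                "evalue": 10.0 ** -rng.uniform(20, 60),
                "bitscore": round(aln * 1.8, 1),
            })
        cols = ["qseqid", "sseqid", "pident", "length", "mismatch",
                "gapopen", "qstart", "qend", "sstart", "send",
                "evalue", "bitscore"]
        return pd.DataFrame(rows, columns=cols)

    hits_cp = _plant_hits(cp_idx, "cp_genome", (95.5, 99.9), (82.0, 99.0))
    hits_mt = _plant_hits(mt_idx, "mt_genome", (81.0, 95.0), (52.0, 90.0))

    pathway_nodes = pd.DataFrame({
        "node_id": [n for n, _ in _PATHWAY_NODES],
        "label": [lab for _, lab in _PATHWAY_NODES],
        "scaffold_ids": [",".join(node_scaffolds.get(n, []))
                         for n, _ in _PATHWAY_NODES],
    })
    pathway_edges = pd.DataFrame(_PATHWAY_EDGES,
                                 columns=["from", "to", "metabolite"])

    counts_df = pd.DataFrame(counts,
                             index=pd.Index(scaffolds, name="scaffold"),
                             columns=samples)
    truth = GroundTruth(
        true_factors=true_factors,
        classes=classes,
        de_genes=[scaffolds[g] for g in de_idx],
        pathway_tiers=pathway_tiers,
        pathway_directions=pathway_dirs,
    )
    return SimulatedData(
        counts=counts_df,
        lengths=pd.Series(lengths, index=counts_df.index, name="length"),
        hits_cp=hits_cp,
        hits_mt=hits_mt,
        pathway_nodes=pathway_nodes,
        pathway_edges=pathway_edges,
        target_samples=[samples[i] for i in target_idx],
        ref_samples=[samples[i] for i in ref_idx],
        truth=truth,
    )


def boundary_partition_fixture() -> tuple[pd.DataFrame, pd.DataFrame,
                                          pd.Series, pd.Series]:
    """Hit tables planted exactly at the classification boundaries.

    Returns ``(hits_cp, hits_mt, lengths, expected_classes)``.  Each
    scaffold isolates one threshold: chloroplast identity 95.0 vs 94.9,
    chloroplast coverage 80 % vs 79.9 %, mitochondrial coverage 50 % vs
    49.9 %, and the scaffold-length gate at 201 vs 200 nt.
    """
    lengths = pd.Series({
        "cp_id_pass": 1000, "cp_id_fail": 1000,
        "cp_cov_pass": 1000, "cp_cov_fail": 1000,
        "mt_cov_pass": 1000, "mt_cov_fail": 1000,
        "len_pass": 201, "len_fail": 200,
        "no_hits": 800,
    }, name="length")

    def _row(q, ident, aln, evalue=1e-30):
        return {"qseqid": q, "sseqid": "ref", "pident": ident,
                "length": aln, "mismatch": 0, "gapopen": 0, "qstart": 1,
                "qend": aln, "sstart": 1, "send": aln, "evalue": evalue,
                "bitscore": aln * 1.8}

    hits_cp = pd.DataFrame([
        _row("cp_id_pass", 95.0, 900),    # identity exactly at threshold
        _row("cp_id_fail", 94.9, 900),
        _row("cp_cov_pass", 98.0, 800),   # coverage exactly 80 %
        _row("cp_cov_fail", 98.0, 799),   # 79.9 %
        _row("len_pass", 99.0, 201),
        _row("len_fail", 99.0, 200),
    ])
    hits_mt = pd.DataFrame([
        _row("mt_cov_pass", 85.0, 500),   # coverage exactly 50 %
        _row("mt_cov_fail", 85.0, 499),   # 49.9 %
        _row("cp_id_fail", 85.0, 600),    # falls through to mitochondrion
    ])
    expected = pd.Series({
        "cp_id_pass": "chloroplast",
        "cp_id_fail": "mitochondrion",   # fails chloroplast, passes mito
        "cp_cov_pass": "chloroplast",
        "cp_cov_fail": "nucleus",
        "mt_cov_pass": "mitochondrion",
        "mt_cov_fail": "nucleus",
        "len_pass": "chloroplast",
        "len_fail": "nucleus",           # length gate
        "no_hits": "nucleus",
    })
    return hits_cp, hits_mt, lengths, expected
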