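"""Synthetic multi-tissue, multi-stage single-cell atlas generator.

The generator plants every statistical structure the downstream stages
estimate, and returns the ground truth needed for parameter-recovery tests:

* three disease stages (healthy, precancer, cancer) with a per-sample
  malignancy level in [0, 1] (healthy fixed at 0);
* epithelial cell types with disjoint marker-gene blocks, including a
  stem-like type whose fraction grows with stage;
* monotone "transition" genes whose log2 mean expression shifts linearly
  with per-cell pseudotime (sample malignancy x cell-type susceptibility;
  stem-like cells carry the full effect, differentiated types half);
* additive expression programs (meta-programs) with non-negative per-cell
  activities; the first program's activity is coupled to pseudotime so that
  one meta-program is genuinely malignancy-associated;
* aneuploid CNV segments acting multiplicatively (2^dosage) on the mean of
  cancer-stage cells;
* mitochondrial genes (``MT-`` prefix) holding a fixed fraction of baseline
  expression;
* heterotypic doublets at a known rate (sums of two same-sample cells,
  depth-rescaled).

Counts are negative-binomial draws (gamma-Poisson) around a per-cell mean
scaled to the cell's library size. All randomness flows from ``config.seed``;
identical config + seed gives bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix

STAGES = ("healthy", "precancer", "cancer")


@dataclass(frozen=True)
class CellTypeSpec:
    name: str
    n_markers: int
    baseline_fraction: float


@dataclass
class AtlasConfig:
    """Study conditions for the synthetic atlas.

    Defaults define the standard benchmark: 3 tissues x 26 samples
    (10 healthy / 8 precancer / 8 cancer) x 250 cells, 2,000 genes, 60
    planted transition genes at +1.5 log2 units of effect at full
    malignancy, 3 expression programs of 40 genes, two aneuploid segments
    in cancer cells, and 8% doublets. Sample counts per stage are chosen
    so that sample-level rank tests can in principle reach FDR < 0.05
    (the discrete Wilcoxon null needs roughly >= 5 samples per side).
    """

    n_tissues: int = 3
    samples_per_stage: Mapping[str, int] = field(
        default_factory=lambda: {"healthy": 10, "precancer": 8, "cancer": 8}
    )
    cells_per_sample: int = 250
    n_genes: int = 2000
    n_mito_genes: int = 40
    mito_fraction: float = 0.08
    cell_types: Sequence[CellTypeSpec] = field(
        default_factory=lambda: (
            CellTypeSpec("STM", 40, 0.25),
            CellTypeSpec("ENT", 40, 0.45),
            CellTypeSpec("SEC", 40, 0.30),
        )
    )
    stem_type: str = "STM"
    stem_fraction_by_stage: Mapping[str, float] = field(
        default_factory=lambda: {"healthy": 0.25, "precancer": 0.4, "cancer": 0.6}
    )
    marker_effect: float = 2.0  # log2 units added to a type's marker genes
    n_transition_genes: int = 60
    transition_effect: float = 1.5  # max |log2FC| at pseudotime 1
    transition_baseline_low: float = -2.0  # log2, relative to the gene-baseline mean
    transition_baseline_high: float = -1.2
    # transition genes co-express with the malignancy-coupled program (they
    # are the genes that program is made of, biologically); log2 per unit
    # of program-0 activity
    transition_program_coupling: float = 0.5
    nonstem_susceptibility: float = 0.5
    n_programs: int = 3
    program_size: int = 40
    program_activity_sd: float = 1.0
    program_loading: float = 2.0  # log2 units per unit activity
    # (chromosome, start index within chromosome, length in genes, log2 dosage)
    cnv_segments: Sequence[tuple[str, int, int, float]] = field(
        default_factory=lambda: (("chr1", 60, 120, 1.0), ("chr3", 60, 120, -1.0))
    )
    doublet_rate: float = 0.08
    heterotypic_prob: float = 0.8
    nb_dispersion: float = 10.0  # NB inverse-dispersion theta; var = mu + mu^2/theta
    depth_mean: float = 2000.0
    n_chromosomes: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        self.cell_types = tuple(
            ct if isinstance(ct, CellTypeSpec) else CellTypeSpec(*ct) for ct in self.cell_types
        )
        self.validate()

    def validate(self) -> None:
        counts = {
            "n_tissues": self.n_tissues,
            "cells_per_sample": self.cells_per_sample,
            "n_genes": self.n_genes,
            "n_chromosomes": self.n_chromosomes,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        for frac in ("mito_fraction", "doublet_rate", "heterotypic_prob"):
            v = getattr(self, frac)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{frac} must lie in [0, 1], got {v}")
        stem = [self.stem_fraction_by_stage[s] for s in STAGES if s in self.stem_fraction_by_stage]
        if any(not 0 <= f <= 1 for f in stem):
            raise ValueError("stem fractions must lie in [0, 1]")
        if any(b < a for a, b in zip(stem, stem[1:])):
            raise ValueError("stem_fraction_by_stage must be non-decreasing healthy->cancer")
        if self.stem_type not in {ct.name for ct in self.cell_types}:
            raise ValueError(f"stem_type {self.stem_type!r} not among cell types")
        structured = (
            self.n_programs * self.program_size
            + self.n_transition_genes
            + sum(ct.n_markers for ct in self.cell_types)
        )
        if structured + self.n_mito_genes > self.n_genes:
            raise ValueError(
                f"structured genes ({structured}) + mitochondrial ({self.n_mito_genes}) "
                f"exceed n_genes ({self.n_genes})"
            )


@dataclass
class GroundTruth:
    """Planted truth for the generated atlas; consumed only by tests and
    recovery benchmarks, never by the estimation stages themselves."""

    cell_type: np.ndarray
    is_doublet: np.ndarray
    stage: np.ndarray
    sample_id: np.ndarray
    tissue: np.ndarray
    pseudotime: np.ndarray
    sample_malignancy: dict[str, float]
    transition_genes: pd.DataFrame  # gene, effect (signed log2 units)
    program_membership: dict[str, list[str]]
    program_activity: np.ndarray  # programs x cells
    cnv_segments: list[dict]  # chromosome, genes, log2_dosage
    aneuploid: np.ndarray  # bool per cell
    doublet_unscaled_totals: np.ndarray  # NaN for singlets

    def cnv_dosage(self, gene_names: np.ndarray) -> np.ndarray:
        """Dense cells x genes matrix of planted log2 dosage."""
        idx = pd.Index(gene_names)
        out = np.zeros((self.cell_type.size, idx.size))
        for seg in self.cnv_segments:
            pos = idx.get_indexer(seg["genes"])
            pos = pos[pos >= 0]
            out[np.ix_(self.aneuploid, pos)] = seg["log2_dosage"]
        return out

    def to_json(self) -> dict:
        return {
            "cell_type": self.cell_type.tolist(),
            "is_doublet": self.is_doublet.astype(bool).tolist(),
            "stage": self.stage.tolist(),
            "sample_id": self.sample_id.tolist(),
            "tissue": self.tissue.tolist(),
            "pseudotime": self.pseudotime.tolist(),
            "sample_malignancy": self.sample_malignancy,
            "transition_genes": self.transition_genes.to_dict(orient="list"),
            "program_membership": self.program_membership,
            "program_activity": self.program_activity.tolist(),
            "cnv_segments": self.cnv_segments,
            "aneuploid": self.aneuploid.astype(bool).tolist(),
            "doublet_unscaled_totals": [
                None if not np.isfinite(v) else float(v) for v in self.doublet_unscaled_totals
            ],
        }

    @classmethod
    def from_json(cls, d: dict) -> "GroundTruth":
        return cls(
            cell_type=np.asarray(d["cell_type"], dtype=object),
            is_doublet=np.asarray(d["is_doublet"], dtype=bool),
            stage=np.asarray(d["stage"], dtype=object),
            sample_id=np.asarray(d["sample_id"], dtype=object),
            tissue=np.asarray(d["tissue"], dtype=object),
            pseudotime=np.asarray(d["pseudotime"], dtype=float),
            sample_malignancy={k: float(v) for k, v in d["sample_malignancy"].items()},
            transition_genes=pd.DataFrame(d["transition_genes"]),
            program_membership={k: list(v) for k, v in d["program_membership"].items()},
            program_activity=np.asarray(d["program_activity"], dtype=float),
            cnv_segments=list(d["cnv_segments"]),
            aneuploid=np.asarray(d["aneuploid"], dtype=bool),
            doublet_unscaled_totals=np.asarray(
                [np.nan if v is None else v for v in d["doublet_unscaled_totals"]], dtype=float
            ),
        )


def _gene_table(config: AtlasConfig) -> pd.DataFrame:
    """Gene names with chromosome assignments; mitochondrial genes on chrM."""
    names = [f"MT-{i + 1}" for i in range(config.n_mito_genes)]
    n_nuc = config.n_genes - config.n_mito_genes
    names += [f"G{i + 1:05d}" for i in range(n_nuc)]
    chrom = ["chrM"] * config.n_mito_genes
    start = list(range(1, config.n_mito_genes + 1))
    per_chrom = math.ceil(n_nuc / config.n_chromosomes)
    for i in range(n_nuc):
        chrom.append(f"chr{i // per_chrom + 1}")
        start.append((i % per_chrom + 1) * 10_000)
    return pd.DataFrame(
        {"gene_id": names, "chromosome": chrom, "start": start},
        index=pd.Index(names, name="gene_name"),
    )


class _AtlasModel:
    """Planted gene-level parameters shared by all cells of one atlas."""

    def __init__(self, config: AtlasConfig, rng: np.random.Generator):
        self.config = config
        self.genes = _gene_table(config)
        names = self.genes.index.to_numpy(dtype=object)
        n = config.n_genes
        nuclear = np.flatnonzero(self.genes["chromosome"].to_numpy() != "chrM")
        mito = np.flatnonzero(self.genes["chromosome"].to_numpy() == "chrM")

        base = np.zeros(n)
        base[nuclear] = rng.normal(0.0, 1.0, nuclear.size)
        # Structured genes (markers, transition genes, programs) are planted on
        # the expressed half of the baseline distribution: signature genes in
        # real data are detectable genes.
        order = nuclear[np.argsort(-base[nuclear])]
        upper = order[: max(nuclear.size // 2, 1)]
        picked = rng.permutation(upper)
        cursor = 0

        self.marker_idx: dict[str, np.ndarray] = {}
        for ct in config.cell_types:
            self.marker_idx[ct.name] = np.sort(picked[cursor : cursor + ct.n_markers])
            cursor += ct.n_markers
        trans = np.sort(picked[cursor : cursor + config.n_transition_genes])
        cursor += config.n_transition_genes
        self.transition_idx = trans
        self.transition_effect = np.full(trans.size, config.transition_effect)
        # transition genes start from a low but detectable baseline so that
        # malignant transformation turns them from rarely to commonly
        # detected -- the regime where fold-change, detection-fraction and
        # rank-correlation screens all see them
        base[trans] = rng.uniform(config.transition_baseline_low, config.transition_baseline_high, trans.size)
        self.program_idx: dict[str, np.ndarray] = {}
        for p in range(config.n_programs):
            self.program_idx[f"MP{p}"] = np.sort(picked[cursor : cursor + config.program_size])
            cursor += config.program_size

        # mitochondrial baseline set so MT- genes hold mito_fraction of the
        # baseline expression budget
        if mito.size and config.mito_fraction > 0:
            nuc_total = np.sum(2.0 ** base[nuclear])
            ratio = config.mito_fraction / (1.0 - config.mito_fraction)
            base[mito] = np.log2(ratio * nuc_total / mito.size)
        self.baseline = base

        # per-gene transition effect vector (signed log2 units at pseudotime 1)
        eff = np.zeros(n)
        eff[trans] = self.transition_effect
        self.effect = eff

        # CNV segments resolved to gene indices
        self.segments: list[dict] = []
        chroms = self.genes["chromosome"].to_numpy()
        for chrom, start_i, length, dosage in config.cnv_segments:
            in_chrom = np.flatnonzero(chroms == chrom)
            seg = in_chrom[start_i : start_i + length]
            if seg.size == 0:
                raise ValueError(f"CNV segment on {chrom} falls outside the gene table")
            self.segments.append(
                {
                    "chromosome": chrom,
                    "genes": [str(g) for g in names[seg]],
                    "log2_dosage": float(dosage),
                    "_idx": seg,
                }
            )

    def log2_mean(
        self,
        cell_type: np.ndarray,
        pseudotime: np.ndarray,
        activity: np.ndarray,
        aneuploid: np.ndarray,
    ) -> np.ndarray:
        """Planted log2 mean surface, genes x cells (before depth scaling)."""
        n_cells = cell_type.size
        lm = np.tile(self.baseline[:, None], (1, n_cells))
        for name, idx in self.marker_idx.items():
            cols = np.flatnonzero(cell_type == name)
            if cols.size:
                lm[np.ix_(idx, cols)] += self.config.marker_effect
        lm += self.effect[:, None] * pseudotime[None, :]
        for p, (mp, idx) in enumerate(self.program_idx.items()):
            lm[idx, :] += self.config.program_loading * activity[p][None, :]
        if self.config.n_programs > 0 and self.config.transition_program_coupling:
            lm[self.transition_idx, :] += (
                self.config.transition_program_coupling * activity[0][None, :]
            )
        for seg in self.segments:
            cols = np.flatnonzero(aneuploid)
            if cols.size:
                lm[np.ix_(seg["_idx"], cols)] += seg["log2_dosage"]
        return lm


def _sample_table(config: AtlasConfig, rng: np.random.Generator, stages: Sequence[str]) -> pd.DataFrame:
    rows = []
    for t in range(config.n_tissues):
        tissue = f"T{t + 1}"
        for stage in stages:
            for i in range(config.samples_per_stage.get(stage, 0)):
                sid = f"{tissue}_{stage}_{i + 1}"
                if stage == "healthy":
                    m = 0.0
                elif stage == "precancer":
                    m = float(rng.uniform(0.15, 0.45))
                else:
                    m = float(rng.uniform(0.7, 1.0))
                rows.append({"sample_id": sid, "tissue": tissue, "stage": stage, "malignancy": m})
    return pd.DataFrame(rows)


def _draw_counts(mean: np.ndarray, theta: float, rng: np.random.Generator) -> np.ndarray:
    """Gamma-Poisson (negative binomial) draws with mean ``mean``."""
    lam = rng.gamma(theta, np.maximum(mean, 0) / theta)
    return rng.poisson(lam)


def generate_atlas(
    config: AtlasConfig, stages: Sequence[str] = STAGES
) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate a full atlas.

    Returns (counts, cell_meta, gene_positions, truth). ``cell_meta`` carries
    barcode, sample_id, tissue, stage, cell_type and pseudotime columns;
    ``gene_positions`` is the (gene, chromosome, start) table.
    """
    rng = np.random.default_rng([int(config.seed), 1])
    model = _AtlasModel(config, rng)
    samples = _sample_table(config, rng, stages)

    blocks: list[sp.csc_matrix] = []
    meta_rows = []
    truth_cols: dict[str, list] = {
        k: []
        for k in (
            "cell_type",
            "is_doublet",
            "stage",
            "sample_id",
            "tissue",
            "pseudotime",
            "aneuploid",
            "unscaled",
        )
    }
    activities: list[np.ndarray] = []

    type_names = np.array([ct.name for ct in config.cell_types], dtype=object)
    base_frac = np.array([ct.baseline_fraction for ct in config.cell_types], dtype=float)
    stem_pos = int(np.flatnonzero(type_names == config.stem_type)[0])

    for _, srow in samples.iterrows():
        sid, stage, malig = srow["sample_id"], srow["stage"], srow["malignancy"]
        n_cells = config.cells_per_sample
        n_doub = int(round(config.doublet_rate * n_cells))
        n_sing = n_cells - n_doub

        stem_f = config.stem_fraction_by_stage.get(stage, base_frac[stem_pos])
        probs = base_frac.copy()
        probs[stem_pos] = 0.0
        if probs.sum() > 0:
            probs = probs / probs.sum() * (1.0 - stem_f)
        probs[stem_pos] = stem_f
        probs = probs / probs.sum()

        ctype = rng.choice(type_names, size=n_sing, p=probs)
        suscept = np.where(ctype == config.stem_type, 1.0, config.nonstem_susceptibility)
        pt = malig * suscept
        act = np.maximum(rng.normal(0.0, config.program_activity_sd, (config.n_programs, n_sing)), 0.0)
        if config.n_programs > 0:
            # first program is malignancy-coupled: its prevalence/intensity
            # grows along the transition while staying heterogeneous within
            # each sample (so per-sample factorisation can still see it)
            act[0] *= 0.3 + pt
        aneup = np.full(n_sing, stage == "cancer")

        lm = model.log2_mean(ctype, pt, act, aneup)
        mu = 2.0**lm
        mu /= mu.sum(axis=0, keepdims=True)
        depth = rng.gamma(10.0, config.depth_mean / 10.0, n_sing)
        counts = _draw_counts(mu * depth[None, :], config.nb_dispersion, rng)

        # doublets: sums of two random same-sample singlets, depth-rescaled
        d_counts = np.zeros((config.n_genes, n_doub), dtype=np.int64)
        d_type = np.empty(n_doub, dtype=object)
        d_pt = np.zeros(n_doub)
        d_unscaled = np.zeros(n_doub)
        d_act = np.zeros((config.n_programs, n_doub))
        for j in range(n_doub):
            a = int(rng.integers(n_sing))
            b = int(rng.integers(n_sing))
            if rng.uniform() < config.heterotypic_prob:
                tries = 0
                while ctype[b] == ctype[a] and tries < 50:
                    b = int(rng.integers(n_sing))
                    tries += 1
            summed = counts[:, a] + counts[:, b]
            total = summed.sum()
            d_unscaled[j] = total
            target = rng.gamma(10.0, config.depth_mean / 10.0)
            if total > 0 and target < total:
                summed = rng.binomial(summed, target / total)
            d_counts[:, j] = summed
            d_type[j] = ctype[a]
            d_pt[j] = 0.5 * (pt[a] + pt[b])
            d_act[:, j] = 0.5 * (act[:, a] + act[:, b])

        block = np.concatenate([counts, d_counts], axis=1)
        blocks.append(sp.csc_matrix(block))
        all_types = np.concatenate([ctype, d_type])
        all_pt = np.concatenate([pt, d_pt])
        all_doub = np.concatenate([np.zeros(n_sing, bool), np.ones(n_doub, bool)])
        all_aneup = np.concatenate([aneup, np.full(n_doub, stage == "cancer")])
        all_unscaled = np.concatenate([np.full(n_sing, np.nan), d_unscaled])
        activities.append(np.concatenate([act, d_act], axis=1))

        for i in range(n_cells):
            meta_rows.append(
                {
                    "barcode": f"{sid}_C{i + 1:04d}",
                    "sample_id": sid,
                    "tissue": srow["tissue"],
                    "stage": stage,
                    "cell_type": all_types[i],
                    "pseudotime": float(all_pt[i]),
                }
            )
        truth_cols["cell_type"].append(all_types)
        truth_cols["is_doublet"].append(all_doub)
        truth_cols["stage"].append(np.full(n_cells, stage, dtype=object))
        truth_cols["sample_id"].append(np.full(n_cells, sid, dtype=object))
        truth_cols["tissue"].append(np.full(n_cells, srow["tissue"], dtype=object))
        truth_cols["pseudotime"].append(all_pt)
        truth_cols["aneuploid"].append(all_aneup)
        truth_cols["unscaled"].append(all_unscaled)

    matrix = sp.hstack(blocks, format="csr")
    meta = pd.DataFrame(meta_rows)
    counts_obj = CountMatrix(matrix, model.genes.drop(columns="gene_id"), meta["barcode"].to_numpy(object))

    names = model.genes.index.to_numpy(dtype=object)
    truth = GroundTruth(
        cell_type=np.concatenate(truth_cols["cell_type"]),
        is_doublet=np.concatenate(truth_cols["is_doublet"]),
        stage=np.concatenate(truth_cols["stage"]),
        sample_id=np.concatenate(truth_cols["sample_id"]),
        tissue=np.concatenate(truth_cols["tissue"]),
        pseudotime=np.concatenate(truth_cols["pseudotime"]),
        sample_malignancy=dict(zip(samples["sample_id"], samples["malignancy"].astype(float))),
        transition_genes=pd.DataFrame(
            {
                "gene": names[model.transition_idx],
                "effect": model.transition_effect,
            }
        ),
        program_membership={mp: [str(g) for g in names[idx]] for mp, idx in model.program_idx.items()},
        program_activity=np.concatenate(activities, axis=1),
        cnv_segments=[{k: v for k, v in seg.items() if k != "_idx"} for seg in model.segments],
        aneuploid=np.concatenate(truth_cols["aneuploid"]),
        doublet_unscaled_totals=np.concatenate(truth_cols["unscaled"]),
    )
    gene_positions = model.genes[["chromosome", "start"]].copy()
    return counts_obj, meta, gene_positions, truth


def generate_reference_only(
    config: AtlasConfig,
) -> tuple[CountMatrix, pd.DataFrame, GroundTruth]:
    """Healthy-stage-only atlas: no CNV and no transition shifts (pseudotime 0)."""
    counts, meta, _, truth = generate_atlas(config, stages=("healthy",))
    return counts, meta, truth


def truth_report(truth: GroundTruth) -> pd.DataFrame:
    """Per-sample summary: stage, cell count, stem fraction, mean pseudotime."""
    cols = ["sample_id", "stage", "n_cells", "stem_fraction", "mean_pseudotime"]
    if truth.sample_id.size == 0:
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame(
        {
            "sample_id": truth.sample_id,
            "stage": truth.stage,
            "is_stem": truth.cell_type == "STM",
            "pseudotime": truth.pseudotime,
        }
    )
    out = (
        df.groupby("sample_id", sort=True)
        .agg(
            stage=("stage", "first"),
            n_cells=("is_stem", "size"),
            stem_fraction=("is_stem", "mean"),
            mean_pseudotime=("pseudotime", "mean"),
        )
        .reset_index()
    )
    return out[cols]
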