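"""End-to-end orchestration: simulate -> qc -> reference -> project -> axis
-> cnv -> mp -> pct, with a deterministic run manifest.

Every stage reads its inputs from the run directory, logs record counts,
and appends SHA-256 checksums of its outputs to the manifest, so two runs
with the same config + seed produce identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from . import axis as axis_mod
from . import cnv as cnv_mod
from . import lsi, metaprograms, pct, qc
from .config import STAGE_ORDER, RunConfig
from .io import CountMatrix, read_mtx_bundle, write_mtx_bundle
from .preprocess import lognorm
from .synthetic import AtlasConfig, generate_atlas, truth_report

logger = logging.getLogger("pcttools")

_STAGE_SEED = {s: 100 + i for i, s in enumerate(STAGE_ORDER)}


def _stage_seed(config: RunConfig, stage: str) -> int:
    return (int(config.seed) * 1000 + _STAGE_SEED[stage]) % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _checksum_dir(d: Path) -> dict[str, str]:
    return {p.name: _sha256(p) for p in sorted(d.iterdir()) if p.is_file()}


def _read_stage(run_dir: Path, name: str) -> tuple[CountMatrix, pd.DataFrame]:
    cm, meta = read_mtx_bundle(run_dir / name)
    if meta is None:
        raise FileNotFoundError(f"{run_dir / name}: missing cell_meta.tsv")
    return cm, meta


def stage_simulate(config: RunConfig, run_dir: Path) -> Path:
    sim = config.simulate
    atlas_cfg = AtlasConfig(
        n_tissues=sim.n_tissues,
        samples_per_stage=sim.samples_per_stage,
        cells_per_sample=sim.cells_per_sample,
        n_genes=sim.n_genes,
        n_mito_genes=sim.n_mito_genes,
        n_transition_genes=sim.n_transition_genes,
        transition_effect=sim.transition_effect,
        n_programs=sim.n_programs,
        program_size=sim.program_size,
        doublet_rate=sim.doublet_rate,
        depth_mean=sim.depth_mean,
        seed=_stage_seed(config, "simulate"),
    )
    counts, meta, _, truth = generate_atlas(atlas_cfg)
    out = write_mtx_bundle(run_dir / "sim", counts, meta, truth.to_json())
    truth_report(truth).to_csv(out / "sample_summary.tsv", sep="\t", index=False)
    logger.info("simulate: %d genes x %d cells", counts.n_genes, counts.n_cells)
    return out


def stage_qc(config: RunConfig, run_dir: Path) -> Path:
    src = run_dir / "sim"
    if not src.exists() and config.in_dir:
        src = Path(config.in_dir)
    cm, meta = read_mtx_bundle(src)
    if meta is None:
        raise FileNotFoundError(f"{src}: missing cell_meta.tsv")
    params = qc.QCParams(**config.qc.model_dump())
    filtered, report = qc.filter_cells(cm, params)
    meta = meta.set_index("barcode").loc[filtered.barcodes].reset_index()
    flags = []
    for sid in meta["sample_id"].unique():
        mask = (meta["sample_id"] == sid).to_numpy()
        flags.append(qc.flag_doublets(filtered.subset_cells(mask), params, seed=_stage_seed(config, "qc")))
    flags_df = pd.concat(flags).loc[filtered.barcodes]
    meta["qc_pass"] = True
    meta["doublet"] = flags_df["doublet"].to_numpy()
    keep = ~meta["doublet"].to_numpy()
    out_cm = filtered.subset_cells(keep)
    out_meta = meta.loc[keep].reset_index(drop=True)
    out = write_mtx_bundle(run_dir / "qc", out_cm, out_meta)
    report.per_cell.to_csv(run_dir / "qc" / "qc_report.tsv", sep="\t")
    truth_path = src / "truth.json"
    if truth_path.exists():
        (run_dir / "qc" / "truth.json").write_text(truth_path.read_text())
    logger.info("qc: %d -> %d cells", report.cells_in, out_cm.n_cells)
    return out


def stage_reference(config: RunConfig, run_dir: Path) -> Path:
    cm, meta = _read_stage(run_dir, "qc")
    healthy = (meta["stage"] == "healthy").to_numpy()
    ref = cm.subset_cells(healthy)
    labels = meta.loc[healthy, "cell_type"].to_numpy(object) if "cell_type" in meta else None
    params = lsi.LSIParams(
        n_variable_genes=config.reference.n_variable_genes,
        n_components=config.reference.n_components,
        resolutions=tuple(config.reference.resolutions),
        snn_k=config.reference.snn_k,
        seed=_stage_seed(config, "reference"),
    )
    model = lsi.build_reference(ref, labels, params)
    out = model.save(run_dir / "model")
    logger.info("reference: %d cells, %d genes, k=%d", healthy.sum(), model.genes.size, model.n_components)
    return out


def stage_project(config: RunConfig, run_dir: Path) -> Path:
    cm, meta = _read_stage(run_dir, "qc")
    model = lsi.LSIModel.load(run_dir / "model")
    diseased = (meta["stage"] != "healthy").to_numpy()
    query = cm.subset_cells(diseased)
    res = lsi.classify_knn(model, lsi.project(model, query), k=config.project.k)
    out = run_dir / "proj"
    out.mkdir(parents=True, exist_ok=True)
    table = pd.DataFrame(
        {
            "barcode": res.barcodes,
            "assigned_label": res.assigned_label,
            "neighbor_votes": res.neighbor_votes,
            "unassigned": res.unassigned_flag,
        }
    )
    table.to_csv(out / "projection.tsv", sep="\t", index=False)
    np.savetxt(out / "embedding.tsv", res.embedding, delimiter="\t")
    logger.info("project: %d diseased cells classified", diseased.sum())
    return out


def _assigned_labels(run_dir: Path) -> pd.Series:
    proj = pd.read_csv(run_dir / "proj" / "projection.tsv", sep="\t")
    return proj.set_index("barcode")["assigned_label"]


def stage_axis(config: RunConfig, run_dir: Path) -> Path:
    cm, meta = _read_stage(run_dir, "qc")
    stem_label = config.axis.stem_label
    assigned = _assigned_labels(run_dir)
    # diseased cells use the projected label; healthy cells their annotation
    label = meta["cell_type"].copy()
    diseased = meta["stage"] != "healthy"
    label.loc[diseased] = assigned.reindex(meta.loc[diseased, "barcode"]).to_numpy()
    meta = meta.assign(cell_type=label)
    norm = lognorm(cm.matrix)
    out = run_dir / "axis"
    out.mkdir(parents=True, exist_ok=True)
    rows, deg_frames = [], []
    for tissue in sorted(meta["tissue"].unique()):
        tmask = (meta["tissue"] == tissue).to_numpy()
        sub_meta = meta.loc[tmask].reset_index(drop=True)
        degs = axis_mod.sample_degs(norm[:, np.flatnonzero(tmask)], cm.gene_names, sub_meta, stem_label)
        if degs.empty:
            continue
        genes = axis_mod.select_axis_genes(
            degs, config.axis.fdr_cutoff, config.axis.lfc_cutoff, config.axis.min_samples
        )
        ax = axis_mod.build_axis(degs, genes)
        sample_stages = sub_meta.groupby("sample_id")["stage"].first()
        positions = ax.positions_for(sample_stages.index.to_numpy(), sample_stages.to_numpy())
        degs.insert(0, "tissue", tissue)
        deg_frames.append(degs)
        for sid, p in positions.items():
            rows.append(
                {"sample_id": sid, "tissue": tissue, "stage": sample_stages[sid], "position": p}
            )
    pd.DataFrame(rows).to_csv(out / "axis.tsv", sep="\t", index=False)
    pd.concat(deg_frames, ignore_index=True).to_csv(out / "degs.tsv", sep="\t", index=False)
    logger.info("axis: positions for %d samples", len(rows))
    return out


def stage_cnv(config: RunConfig, run_dir: Path) -> Path:
    cm, meta = _read_stage(run_dir, "qc")
    norm = lognorm(cm.matrix, scale=config.cnv.norm_scale)
    ref_mask = (meta["stage"] == config.cnv.reference_stage).to_numpy()
    cnv = cnv_mod.infer_cnv(
        norm, cm.genes, ref_mask, window=config.cnv.window, clip=config.cnv.clip,
        barcodes=cm.barcodes,
    )
    scores = cnv_mod.cnv_score(cnv)
    out = run_dir / "cnv"
    out.mkdir(parents=True, exist_ok=True)
    scores.to_csv(out / "cnv_scores.tsv", sep="\t")
    logger.info("cnv: scored %d cells over %d genes", cnv.values.shape[0], cnv.values.shape[1])
    return out


def stage_mp(config: RunConfig, run_dir: Path) -> Path:
    cm, meta = _read_stage(run_dir, "qc")
    stem_label = config.axis.stem_label
    assigned = _assigned_labels(run_dir)
    seed = _stage_seed(config, "mp")
    norm = lognorm(cm.matrix)
    diseased_stem = (
        (meta["stage"] != "healthy")
        & (assigned.reindex(meta["barcode"]).to_numpy() == stem_label)
    ).to_numpy()
    ranks = range(config.mp.rank_min, config.mp.rank_max + 1)
    programs = []
    for sid in sorted(meta.loc[diseased_stem, "sample_id"].unique()):
        cols = np.flatnonzero(diseased_stem & (meta["sample_id"] == sid).to_numpy())
        if cols.size <= config.mp.rank_min:
            continue
        sub = norm[:, cols]
        # restrict to the most variable genes to keep factorisation honest and fast
        from .preprocess import gene_variance

        var = gene_variance(sub)
        top = np.argsort(-var, kind="stable")[: config.mp.nmf_max_genes]
        v = metaprograms.nmf_input(sub[np.sort(top)])
        try:
            programs.extend(
                metaprograms.nmf_programs(
                    v, cm.gene_names[np.sort(top)], sid, ranks, seed=seed,
                    n_top_genes=config.mp.n_top_genes,
                )
            )
        except ValueError as exc:
            logger.warning("mp: sample %s skipped (%s)", sid, exc)
    mps = metaprograms.consensus_modules(
        programs, range(config.mp.k_min, config.mp.k_max + 1), seed=seed
    )
    # AUCell activity of each MP over all diseased stem cells
    cols = np.flatnonzero(diseased_stem)
    act = {}
    for mp_id, genes in mps.modules.items():
        act[mp_id] = metaprograms.aucell(
            norm[:, cols], cm.gene_names, genes, config.mp.top_fraction, seed=seed
        )
    activity = pd.DataFrame(act, index=cm.barcodes[cols]).T
    out = run_dir / "mp"
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "modules.json", "w") as fh:
        json.dump(mps.modules, fh, sort_keys=True, indent=1)
    prog_rows = [
        {
            "sample_id": p.sample_id,
            "factor": p.factor_index,
            "rank": p.rank_used,
            "gene": g,
            "loading": float(l),
        }
        for p in programs
        for g, l in zip(p.top_genes, p.loadings)
    ]
    pd.DataFrame(prog_rows).to_csv(out / "programs.tsv", sep="\t", index=False)
    activity.to_csv(out / "activity.tsv", sep="\t")
    if "pseudotime" in meta.columns and len(activity):
        pt = meta.set_index("barcode")["pseudotime"].reindex(activity.columns).to_numpy()
        corr = metaprograms.mp_correlations(activity, pt)
        corr.to_csv(out / "mp_correlations.tsv", sep="\t", index=False)
    logger.info("mp: %d programs -> %d meta-programs", len(programs), len(mps.modules))
    return out


def stage_pct(config: RunConfig, run_dir: Path) -> Path:
    cm, meta = _read_stage(run_dir, "qc")
    stem_label = config.axis.stem_label
    assigned = _assigned_labels(run_dir)
    seed = _stage_seed(config, "pct")
    norm = lognorm(cm.matrix)
    activity = pd.read_csv(run_dir / "mp" / "activity.tsv", sep="\t", index_col=0)
    with open(run_dir / "mp" / "modules.json") as fh:
        modules = json.load(fh)
    stem_assigned = assigned.reindex(meta["barcode"]).to_numpy() == stem_label
    is_stem = np.where((meta["stage"] != "healthy").to_numpy(), stem_assigned, (meta["cell_type"] == stem_label).to_numpy())
    if "pseudotime" not in meta.columns:
        raise ValueError("cell_meta must carry a per-cell 'pseudotime' column for the pct stage")

    signatures = {}
    for mp_id in modules:
        candidates: dict[str, pct.CandidateSets] = {}
        for tissue in sorted(meta["tissue"].unique()):
            tmask = (meta["tissue"] == tissue).to_numpy()
            sub_meta = meta.loc[tmask].reset_index(drop=True)
            sub_norm = norm[:, np.flatnonzero(tmask)]
            sub_stem = is_stem[tmask]
            try:
                pb, _ = pct.pseudo_bulk_degs(
                    sub_norm, cm.gene_names, sub_meta.assign(cell_type=np.where(sub_stem, stem_label, "other")),
                    stem_label, config.pct.fdr_cutoff, config.pct.pseudo_bulk_lfc,
                )
            except ValueError as exc:
                logger.warning("pct: tissue %s pseudo-bulk skipped (%s)", tissue, exc)
                continue
            dstem = np.flatnonzero(sub_stem & (sub_meta["stage"] != "healthy").to_numpy())
            if dstem.size < 30:
                logger.warning("pct: tissue %s has %d diseased stem cells; skipped", tissue, dstem.size)
                continue
            stem_norm = sub_norm[:, dstem]
            # trajectory core clusters = start / end quartiles of the input
            # pseudotime (the trajectory's origin and terminal states)
            pt_stem = sub_meta.loc[dstem, "pseudotime"].to_numpy()
            q1, q3 = np.quantile(pt_stem, [0.25, 0.75])
            clusters = np.where(pt_stem <= q1, "start", np.where(pt_stem >= q3, "end", "mid"))
            try:
                sub_set, _ = pct.subcluster_degs(
                    stem_norm, cm.gene_names, clusters, [("end", "start"), ("start", "end")],
                    config.pct.subcluster_lfc, config.pct.pct1_cutoff, config.pct.ratio_cutoff,
                )
                trans = pct.transition_genes(
                    stem_norm, cm.gene_names, pt_stem, config.pct.fdr_cutoff
                )
            except ValueError as exc:
                logger.warning("pct: tissue %s skipped (%s)", tissue, exc)
                continue
            bc = sub_meta.loc[dstem, "barcode"]
            act = activity.loc[mp_id].reindex(bc)
            if act.isna().all() or act.nunique() <= 1:
                continue
            act_filled = act.fillna(act.mean()).to_numpy()
            mp_table = pct.mp_genes(stem_norm, cm.gene_names, act_filled, config.pct.fdr_cutoff)
            candidates[tissue] = pct.CandidateSets(pb, sub_set, trans, mp_table)
        signatures[mp_id] = pct.derive_pct(
            candidates, mp_id, config.pct.top_n, config.pct.use_mp_rho
        )
    out = run_dir / "pct"
    out.mkdir(parents=True, exist_ok=True)
    rows = [
        {"mp_id": mp_id, "rank": i + 1, "gene": g, "gmean_score": float(s)}
        for mp_id, sig in sorted(signatures.items())
        for i, (g, s) in enumerate(zip(sig.genes, sig.gmean_score))
    ]
    pd.DataFrame(rows, columns=["mp_id", "rank", "gene", "gmean_score"]).to_csv(
        out / "pct_signature.tsv", sep="\t", index=False
    )
    logger.info("pct: %d signatures written", len(signatures))
    return out


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "reference": stage_reference,
    "project": stage_project,
    "axis": stage_axis,
    "cnv": stage_cnv,
    "mp": stage_mp,
    "pct": stage_pct,
}


def run_all(config: RunConfig) -> dict:
    """Run every enabled stage in order and write run_manifest.json."""
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    dump = config.model_dump(mode="json")
    dump.pop("out_dir", None)  # paths are not part of the scientific config
    dump.pop("in_dir", None)
    config_dump = json.dumps(dump, sort_keys=True)
    manifest: dict = {
        "config_sha256": hashlib.sha256(config_dump.encode()).hexdigest(),
        "seed": int(config.seed),
        "format_version": config.format_version,
        "stages": {},
    }
    for stage in STAGE_ORDER:
        if stage not in config.stages:
            continue
        logger.info("running stage %s", stage)
        try:
            out = _STAGE_FUNCS[stage](config, run_dir)
        except Exception as exc:
            manifest["failed_stage"] = stage
            with open(run_dir / "run_manifest.json", "w") as fh:
                json.dump(manifest, fh, sort_keys=True, indent=1)
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = _checksum_dir(Path(out))
    with open(run_dir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1)
    return manifest
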