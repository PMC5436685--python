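"""End-to-end pipeline orchestration with on-disk artifacts.

Stages: simulate -> ica (per cohort subset: high, low, all) -> identify ->
cgca -> stats -> predict -> report.  Each stage reads the previous stage's
artifacts from the output directory, writes its own (NIfTI volumes, TSV
tables, JSON sidecars), and appends an entry to the run manifest with
checksums, wall time and the seeds it consumed.  Sub-seeds are derived by
hashing (master_seed, stage, item), so they are stable regardless of
execution order.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import cgca as cgca_mod
from . import ica as ica_mod
from . import identify as id_mod
from . import predict as pred_mod
from . import synthetic as syn
from .utils import derive_seed

log = logging.getLogger(__name__)

SUBSETS = ("high", "low", "all")
STAGES = ("simulate", "ica", "identify", "cgca", "stats", "predict", "report")


@dataclass
class PipelineConfig:
    """Full pipeline configuration (YAML-serializable)."""

    master_seed: int = 0
    # cohort
    n_high: int = 15
    n_low: int = 15
    n_volumes_raw: int = 255
    n_discard: int = 5
    tr_seconds: float = 2.0
    grid_dims: tuple[int, int, int] = (24, 24, 12)
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    snr: float = 2.0
    n_nuisance: int = 2
    smooth_fwhm_mm: float = 8.0
    blobs_per_network: int = 2
    blob_radius_vox: float = 2.0
    # ica
    ica_k: int | str = "mdl"
    ica_tol: float = 1e-6
    ica_max_iter: int = 500
    normalize_variance: bool = False
    # identify
    identify_q: float = 0.05
    # cgca
    cgca_order: int | str = "sc"
    cgca_max_order: int = 5
    n_surrogates: int = 99
    cgca_q: float = 0.05
    detrend: bool = False
    # stats / predict
    screen_q: float = 0.05
    svr_C: float = 1.0
    svr_epsilon: float = 0.1
    predict_edges: tuple = (("AfN", "VN"), ("DAN", "VAN"))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_dims"] = list(self.grid_dims)
        d["voxel_size_mm"] = list(self.voxel_size_mm)
        d["predict_edges"] = [list(e) for e in self.predict_edges]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "grid_dims" in d:
            d["grid_dims"] = tuple(d["grid_dims"])
        if "voxel_size_mm" in d:
            d["voxel_size_mm"] = tuple(d["voxel_size_mm"])
        if "predict_edges" in d:
            d["predict_edges"] = tuple(tuple(e) for e in d["predict_edges"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def cohort_config(self) -> syn.CohortConfig:
        grid = syn.VoxelGrid(dims=self.grid_dims, voxel_size_mm=self.voxel_size_mm)
        coupling = syn.CouplingSpec()
        templates = syn.make_templates(
            grid, n_networks=coupling.n_networks,
            blobs_per_network=self.blobs_per_network,
            blob_radius_vox=self.blob_radius_vox,
            seed=derive_seed(self.master_seed, "templates"),
            names=coupling.names,
        )
        return syn.CohortConfig(
            n_high=self.n_high, n_low=self.n_low,
            n_volumes_raw=self.n_volumes_raw, n_discard=self.n_discard,
            tr_seconds=self.tr_seconds, grid=grid, templates=templates,
            coupling=coupling, snr=self.snr, n_nuisance=self.n_nuisance,
            master_seed=self.master_seed,
        )


# ---------------------------------------------------------------------------
# NIfTI helpers


def save_volumes_nifti(data: np.ndarray, grid: syn.VoxelGrid, path: Path) -> None:
    """Write (time, voxels) data as a 4-D NIfTI volume."""
    vol = data.reshape(data.shape[0], *grid.dims).transpose(1, 2, 3, 0)
    nib.save(nib.Nifti1Image(vol.astype(np.float32), grid.affine()), str(path))


def load_volumes_nifti(path: Path) -> tuple[np.ndarray, syn.VoxelGrid]:
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj, dtype=np.float64)
    dims = arr.shape[:3]
    vs = tuple(float(z) for z in img.header.get_zooms()[:3])
    # (nx, ny, nz, T) -> (T, V) with C-ordered voxel flattening
    data = arr.transpose(3, 0, 1, 2).reshape(arr.shape[3], -1)
    return data, syn.VoxelGrid(dims=tuple(int(d) for d in dims), voxel_size_mm=vs)


def save_templates_nifti(templates: syn.TemplateSet, path: Path) -> None:
    stack = templates.masks.T.reshape(*templates.grid.dims, len(templates.names))
    nib.save(nib.Nifti1Image(stack.astype(np.uint8), templates.grid.affine()), str(path))
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump({"names": list(templates.names)}, fh)


def load_templates_nifti(path: Path) -> syn.TemplateSet:
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj)
    grid = syn.VoxelGrid(
        dims=tuple(int(d) for d in arr.shape[:3]),
        voxel_size_mm=tuple(float(z) for z in img.header.get_zooms()[:3]),
    )
    with open(path.with_suffix(".json")) as fh:
        names = tuple(json.load(fh)["names"])
    masks = arr.transpose(3, 0, 1, 2).reshape(arr.shape[3], -1).astype(bool)
    return syn.TemplateSet(grid=grid, names=names, masks=masks)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# manifest


@dataclass
class RunManifest:
    path: Path
    entries: list = field(default_factory=list)

    @classmethod
    def open(cls, out_dir: Path) -> "RunManifest":
        path = out_dir / "manifest.json"
        entries = []
        if path.exists():
            entries = json.loads(path.read_text()).get("stages", [])
        return cls(path=path, entries=entries)

    def record(self, stage: str, cfg: PipelineConfig, outputs: list[Path],
               seeds: dict, wall_seconds: float) -> None:
        self.entries = [e for e in self.entries if e["stage"] != stage]
        self.entries.append({
            "stage": stage,
            "config_hash": cfg.config_hash(),
            "outputs": {str(p.name): _sha256(p) for p in outputs if p.is_file()},
            "seeds": seeds,
            "wall_seconds": round(wall_seconds, 3),
        })
        self.path.write_text(json.dumps({"stages": self.entries}, indent=1))

    def stage_entry(self, stage: str) -> dict | None:
        for e in self.entries:
            if e["stage"] == stage:
                return e
        return None


def _require(out_dir: Path, relpaths: list[str], needed_by: str, produced_by: str) -> None:
    for rel in relpaths:
        if not (out_dir / rel).exists():
            raise FileNotFoundError(
                f"stage '{needed_by}' needs '{rel}'; run stage '{produced_by}' first"
            )


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: PipelineConfig, out_dir: Path) -> list[Path]:
    t0 = time.perf_counter()
    cdir = out_dir / "cohort"
    cdir.mkdir(parents=True, exist_ok=True)
    ccfg = cfg.cohort_config()
    subjects, table = syn.simulate_cohort(ccfg)
    outputs = []
    truth = {}
    for ds in subjects:
        p = cdir / f"sub-{ds.subject_id}.nii"
        save_volumes_nifti(ds.data, ccfg.grid, p)
        outputs.append(p)
        truth[ds.subject_id] = {
            "a_eff": np.asarray(ds.true_coupling).tolist(),
            "names": list(ccfg.coupling.names),
        }
    table.to_csv(cdir / "behavioral.csv", index=False)
    with open(cdir / "truth.json", "w") as fh:
        json.dump(truth, fh)
    save_templates_nifti(ccfg.templates, cdir / "templates.nii")
    outputs += [cdir / "behavioral.csv", cdir / "truth.json", cdir / "templates.nii"]
    man = RunManifest.open(out_dir)
    man.record("simulate", cfg, outputs,
               {"master_seed": cfg.master_seed}, time.perf_counter() - t0)
    return outputs


def _load_cohort(cfg: PipelineConfig, out_dir: Path):
    """Load subjects, apply volume discard and smoothing.

    Returns both the smoothed subjects (for decomposition) and the
    unsmoothed ones: dimensionality estimation assumes spatially white
    noise, which smoothing destroys, so MDL runs on pre-smoothing data.
    """
    cdir = out_dir / "cohort"
    table = pd.read_csv(cdir / "behavioral.csv")
    templates = load_templates_nifti(cdir / "templates.nii")
    subjects, raw_subjects = [], []
    for _, row in table.iterrows():
        data, grid = load_volumes_nifti(cdir / f"sub-{row.subject_id}.nii")
        ds = syn.SubjectDataset(
            data=data, tr_seconds=cfg.tr_seconds,
            behavioral={s: row[s] for s in syn.SCALE_NAMES},
            group=row.group, subject_id=row.subject_id, seed=int(row.seed),
        )
        ds = syn.discard_initial_volumes(ds, cfg.n_discard)
        raw_subjects.append(ds)
        if cfg.smooth_fwhm_mm > 0:
            ds = syn.smooth_spatial(ds, grid, cfg.smooth_fwhm_mm)
        subjects.append(ds)
    return subjects, raw_subjects, table, templates


def stage_ica(cfg: PipelineConfig, out_dir: Path) -> list[Path]:
    _require(out_dir, ["cohort/behavioral.csv"], "ica", "simulate")
    t0 = time.perf_counter()
    subjects, raw_subjects, table, templates = _load_cohort(cfg, out_dir)
    outputs = []
    seeds = {}
    for subset in SUBSETS:
        keep = [i for i, s in enumerate(subjects)
                if subset == "all" or s.group == subset]
        sub = [subjects[i] for i in keep]
        sdir = out_dir / "ica" / subset
        sdir.mkdir(parents=True, exist_ok=True)
        if cfg.ica_k == "mdl":
            # per-subject MDL on pre-smoothing data; median across subjects
            est = [ica_mod.estimate_ndim_mdl(raw_subjects[i].data) for i in keep]
            k = int(np.median(est))
            log.info("%s subset: per-subject MDL estimates %s -> k=%d", subset, est, k)
            k = max(k, len(templates.names))
        else:
            k = int(cfg.ica_k)
        k = min(k, min(s.n_volumes for s in sub) - 1)
        reduced, ops = ica_mod.concat_and_reduce(
            sub, k, normalize_variance=cfg.normalize_variance)
        seed = derive_seed(cfg.master_seed, "ica", subset)
        seeds[f"ica_{subset}"] = seed
        res = ica_mod.fastica_decompose(
            reduced, ops, seed=seed, tol=cfg.ica_tol, max_iter=cfg.ica_max_iter)
        res = ica_mod.back_reconstruct(res, ops, sub)

        grid = templates.grid
        save_volumes_nifti(res.group_maps, grid, sdir / "group_maps.nii")
        pd.DataFrame(res.group_timecourses).to_csv(
            sdir / "group_timecourses.tsv", sep="\t", index=False)
        with open(sdir / "ica_info.json", "w") as fh:
            json.dump({"k": k, "convergence": res.convergence,
                       "explained_variance": ops.explained_variance_fraction,
                       "subjects": [s.subject_id for s in sub]}, fh)
        for s, m, tc in zip(sub, res.subject_maps, res.subject_timecourses):
            save_volumes_nifti(m, grid, sdir / f"maps_sub-{s.subject_id}.nii")
            pd.DataFrame(tc).to_csv(
                sdir / f"tc_sub-{s.subject_id}.tsv", sep="\t", index=False)
        outputs += sorted(sdir.iterdir())
    man = RunManifest.open(out_dir)
    man.record("ica", cfg, outputs, seeds, time.perf_counter() - t0)
    return outputs


def _load_subset_maps(out_dir: Path, subset: str):
    sdir = out_dir / "ica" / subset
    with open(sdir / "ica_info.json") as fh:
        info = json.load(fh)
    maps = {}
    for sid in info["subjects"]:
        data, _ = load_volumes_nifti(sdir / f"maps_sub-{sid}.nii")
        maps[sid] = data
    group_maps, _ = load_volumes_nifti(sdir / "group_maps.nii")
    return info, group_maps, maps


def stage_identify(cfg: PipelineConfig, out_dir: Path) -> list[Path]:
    _require(out_dir, ["ica/all/ica_info.json"], "identify", "ica")
    t0 = time.perf_counter()
    templates = load_templates_nifti(out_dir / "cohort" / "templates.nii")
    idir = out_dir / "identify"
    idir.mkdir(parents=True, exist_ok=True)
    outputs = []
    assignments = {}
    subject_maps_by_subset = {}
    rows = []
    for subset in SUBSETS:
        info, group_maps, subj_maps = _load_subset_maps(out_dir, subset)
        asn = id_mod.assign_components(group_maps, templates)
        assignments[subset] = asn
        subject_maps_by_subset[subset] = (info, subj_maps)
        for name in templates.names:
            rows.append({
                "subset": subset, "network": name,
                "component": asn.chosen[name], "score": asn.scores[name],
                "runner_up": asn.runner_up[name],
            })
    asn_path = idir / "assignment.tsv"
    pd.DataFrame(rows).to_csv(asn_path, sep="\t", index=False)
    outputs.append(asn_path)

    # one-sample spatial maps per group (each group's own decomposition)
    one_sample_masks = {"high": {}, "low": {}}
    grid = templates.grid
    for group in ("high", "low"):
        info, subj_maps = subject_maps_by_subset[group]
        for name in templates.names:
            comp = assignments[group].chosen[name]
            stack = np.stack([subj_maps[sid][comp] for sid in info["subjects"]])
            res = id_mod.group_spatial_ttest(stack, "one_sample", q=cfg.identify_q)
            one_sample_masks[group][name] = res.sig_mask
            p = idir / f"onesample_{group}_{name}_tmap.nii"
            save_volumes_nifti(res.t_map[None, :], grid, p)
            pm = idir / f"onesample_{group}_{name}_mask.nii"
            save_volumes_nifti(res.sig_mask[None, :].astype(float), grid, pm)
            outputs += [p, pm]

    combined = id_mod.build_combined_mask(one_sample_masks["high"], one_sample_masks["low"])
    # two-sample comparison inside the combined mask, using the all-subjects
    # decomposition so both groups' maps live in the same component space
    info_all, subj_maps_all = subject_maps_by_subset["all"]
    behav = pd.read_csv(out_dir / "cohort" / "behavioral.csv").set_index("subject_id")
    for name in templates.names:
        comp = assignments["all"].chosen[name]
        hi = np.stack([subj_maps_all[sid][comp] for sid in info_all["subjects"]
                       if behav.loc[sid, "group"] == "high"])
        lo = np.stack([subj_maps_all[sid][comp] for sid in info_all["subjects"]
                       if behav.loc[sid, "group"] == "low"])
        mask = combined[name]
        pmask = idir / f"combined_{name}_mask.nii"
        save_volumes_nifti(mask[None, :].astype(float), grid, pmask)
        outputs.append(pmask)
        if mask.any():
            res2 = id_mod.group_spatial_ttest(
                hi, "two_sample", q=cfg.identify_q, mask=mask, subject_maps_b=lo)
            p2 = idir / f"twosample_{name}_tmap.nii"
            save_volumes_nifti(res2.t_map[None, :], grid, p2)
            outputs.append(p2)
    man = RunManifest.open(out_dir)
    man.record("identify", cfg, outputs, {}, time.perf_counter() - t0)
    return outputs


def stage_cgca(cfg: PipelineConfig, out_dir: Path) -> list[Path]:
    _require(out_dir, ["identify/assignment.tsv"], "cgca", "identify")
    t0 = time.perf_counter()
    gdir = out_dir / "cgca"
    gdir.mkdir(parents=True, exist_ok=True)
    asn = pd.read_csv(out_dir / "identify" / "assignment.tsv", sep="\t")
    asn_all = asn[asn.subset == "all"].set_index("network")
    templates = load_templates_nifti(out_dir / "cohort" / "templates.nii")
    names = tuple(templates.names)
    comp_idx = [int(asn_all.loc[n, "component"]) for n in names]
    with open(out_dir / "ica" / "all" / "ica_info.json") as fh:
        info = json.load(fh)
    behav = pd.read_csv(out_dir / "cohort" / "behavioral.csv").set_index("subject_id")

    subject_ts = {}
    for sid in info["subjects"]:
        tc = pd.read_csv(out_dir / "ica" / "all" / f"tc_sub-{sid}.tsv", sep="\t").to_numpy()
        ts = tc[:, comp_idx]
        ts = ts - ts.mean(axis=0)
        if cfg.detrend:
            from scipy.signal import detrend as _dt
            ts = _dt(ts, axis=0)
        subject_ts[sid] = ts

    if cfg.cgca_order == "sc":
        orders = [cgca_mod.select_order_sc(ts, cfg.cgca_max_order)
                  for ts in subject_ts.values()]
        order = Counter(orders).most_common(1)[0][0]
        log.info("modal SC order across subjects: %d (choices: %s)",
                 order, dict(Counter(orders)))
    else:
        order = int(cfg.cgca_order)

    seeds = {}
    frames = []
    for sid, ts in subject_ts.items():
        seed = derive_seed(cfg.master_seed, "cgca", sid)
        seeds[f"cgca_{sid}"] = seed
        gm = cgca_mod.gc_all_pairs_normalized(
            ts, order=order, n_surrogates=cfg.n_surrogates, seed=seed, names=names)
        frames.append(gm.to_frame(subject_id=sid))
    table = pd.concat(frames, ignore_index=True)
    table["group"] = table["subject_id"].map(behav["group"])
    tpath = gdir / "edges_subject.tsv"
    table.to_csv(tpath, sep="\t", index=False)
    outputs = [tpath]

    summary = {}
    for group in ("high", "low"):
        gt = cgca_mod.group_gc_test(table[table.group == group], q=cfg.cgca_q)
        gp = gdir / f"group_edges_{group}.tsv"
        gt.to_csv(gp, sep="\t", index=False)
        outputs.append(gp)
        summary[group] = {
            f"{r.source}->{r.target}": {"mean_z": r.mean_z, "p_fdr": r.p_fdr,
                                        "significant": bool(r.significant)}
            for r in gt.itertuples()
        }
    with open(gdir / "group_summary.json", "w") as fh:
        json.dump({"order": order, "groups": summary}, fh, indent=1)
    outputs.append(gdir / "group_summary.json")
    man = RunManifest.open(out_dir)
    man.record("cgca", cfg, outputs, seeds, time.perf_counter() - t0)
    return outputs


def stage_stats(cfg: PipelineConfig, out_dir: Path) -> list[Path]:
    _require(out_dir, ["cgca/edges_subject.tsv"], "stats", "cgca")
    t0 = time.perf_counter()
    sdir = out_dir / "stats"
    sdir.mkdir(parents=True, exist_ok=True)
    table = pd.read_csv(out_dir / "cgca" / "edges_subject.tsv", sep="\t")
    behav = pd.read_csv(out_dir / "cohort" / "behavioral.csv")
    edges = [tuple(e) for e in cfg.predict_edges]
    screen = pred_mod.correlation_screen(
        table[["subject_id", "source", "target", "z"]], behav,
        edges=edges, q=cfg.screen_q)
    spath = sdir / "correlations.tsv"
    screen.to_csv(spath, sep="\t", index=False)
    man = RunManifest.open(out_dir)
    man.record("stats", cfg, [spath], {}, time.perf_counter() - t0)
    return [spath]


def stage_predict(cfg: PipelineConfig, out_dir: Path) -> list[Path]:
    _require(out_dir, ["cgca/edges_subject.tsv"], "predict", "cgca")
    t0 = time.perf_counter()
    pdir = out_dir / "predict"
    pdir.mkdir(parents=True, exist_ok=True)
    table = pd.read_csv(out_dir / "cgca" / "edges_subject.tsv", sep="\t")
    behav = pd.read_csv(out_dir / "cohort" / "behavioral.csv")
    hi = behav[behav.group == "high"].sort_values("subject_id")
    outputs = []
    results = {}
    for src, tgt in [tuple(e) for e in cfg.predict_edges]:
        sub = table[(table.source == src) & (table.target == tgt)]
        sub = sub[sub.subject_id.isin(hi.subject_id)].sort_values("subject_id")
        feats = sub["z"].to_numpy().reshape(-1, 1)
        scores = hi.set_index("subject_id").loc[sub.subject_id, "Loneliness"].to_numpy()
        res = pred_mod.svr_loocv_predict(feats, scores, C=cfg.svr_C,
                                         epsilon=cfg.svr_epsilon)
        key = f"{src}->{tgt}"
        results[key] = {"rmsep": res.rmsep, "r": res.r_pred_actual, "p": res.p,
                        "n_models": res.n_models}
        scat = pd.DataFrame({"subject_id": sub.subject_id.to_numpy(),
                             "actual": res.actual, "predicted": res.predictions})
        sp = pdir / f"scatter_{src}_to_{tgt}.tsv"
        scat.to_csv(sp, sep="\t", index=False)
        outputs.append(sp)
    jp = pdir / "prediction.json"
    with open(jp, "w") as fh:
        json.dump(results, fh, indent=1)
    outputs.append(jp)
    man = RunManifest.open(out_dir)
    man.record("predict", cfg, outputs, {}, time.perf_counter() - t0)
    return outputs


def stage_report(cfg: PipelineConfig, out_dir: Path) -> list[Path]:
    _require(out_dir, ["cgca/group_summary.json", "predict/prediction.json"],
             "report", "predict")
    t0 = time.perf_counter()
    with open(out_dir / "cgca" / "group_summary.json") as fh:
        gsum = json.load(fh)
    with open(out_dir / "predict" / "prediction.json") as fh:
        pred = json.load(fh)
    screen = pd.read_csv(out_dir / "stats" / "correlations.tsv", sep="\t")
    lines = ["# Pipeline report", "",
             f"VAR order used: {gsum['order']}", ""]
    for group, edges in gsum["groups"].items():
        sig = [e for e, v in edges.items() if v["significant"]]
        lines.append(f"## {group} group: significant edges")
        lines += [f"- {e} (mean z = {edges[e]['mean_z']:.2f}, "
                  f"p_fdr = {edges[e]['p_fdr']:.2g})" for e in sig] or ["- none"]
        lines.append("")
    lines.append("## Significant behavioral correlations")
    sig_rows = screen[screen.significant]
    for r in sig_rows.itertuples():
        lines.append(f"- {r.group}: {r.source}->{r.target} vs {r.scale}: "
                     f"r = {r.r:.3f}, p_fdr = {r.p_fdr:.3g}")
    if sig_rows.empty:
        lines.append("- none")
    lines.append("")
    lines.append("## Loneliness prediction (high-loneliness group, LOOCV SVR)")
    for edge, v in pred.items():
        lines.append(f"- {edge}: RMSEP = {v['rmsep']:.3f}, "
                     f"r(pred, actual) = {v['r']:.3f} (p = {v['p']:.3g})")
    rp = out_dir / "report.md"
    rp.write_text("\n".join(lines) + "\n")
    man = RunManifest.open(out_dir)
    man.record("report", cfg, [rp], {}, time.perf_counter() - t0)
    return [rp]


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "ica": stage_ica,
    "identify": stage_identify,
    "cgca": stage_cgca,
    "stats": stage_stats,
    "predict": stage_predict,
    "report": stage_report,
}


def run_stage(name: str, cfg: PipelineConfig, out_dir: str | Path,
              force: bool = False) -> list[Path]:
    """Run one named stage; skip if its manifest entry is current unless forced."""
    if name not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage '{name}'; stages are {STAGES}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    man = RunManifest.open(out_dir)
    entry = man.stage_entry(name)
    if entry and not force and entry["config_hash"] == cfg.config_hash():
        existing = [out_dir.glob(f"**/{n}") for n in entry["outputs"]]
        if all(any(g) for g in existing):
            log.info("stage '%s' up to date; skipping (use force to rerun)", name)
            return []
    log.info("running stage '%s'", name)
    return _STAGE_FUNCS[name](cfg, out_dir)


def run_all(cfg: PipelineConfig, out_dir: str | Path, force: bool = False) -> None:
    """Run the full pipeline in dependency order."""
    for name in STAGES:
        run_stage(name, cfg, out_dir, force=force)
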