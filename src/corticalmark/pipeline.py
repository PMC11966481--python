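"""End-to-end orchestration: simulate -> ReHo -> effect maps -> spin -> RVI.

Stages communicate only through files in the output directory, each stage
draws from its own RNG stream (derived from the master seed by stage name,
so adding a stage never perturbs another stage's draws), and every run
writes a manifest recording the config, seeds and input digests.  Re-running
with the same config reproduces byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import RegionalMeasureTable, TemplateVector
from .effects import DeficitPatternModel
from .io import (
    read_atlas,
    read_bold,
    read_regional_table,
    read_template,
    read_tsv,
    read_yaml,
    write_atlas,
    write_json,
    write_regional_table,
    write_tsv,
    write_volume,
)
from .reho import average_hemispheres, extract_regional_means, reho_map
from .rvi import RVIModel
from .simulate import make_toy_atlas, simulate_bold
from .spatial import spin_permutation_p

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs", "stage_seed"]

STAGES = ["simulate", "reho", "esmap", "spin", "rvi"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Independent per-stage seed derived from the master seed by name."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Configuration of a full synthetic run (see YAML example in docs)."""

    outdir: str
    seed: int = 0
    stages: list = field(default_factory=lambda: list(STAGES))
    grid_shape: tuple = (24, 24, 24)
    n_region_pairs: int = 8
    n_timepoints: int = 60
    n_cases: int = 30
    n_controls: int = 30
    base_coherence: float = 0.35
    deficit_coherence_delta: object = None  # per-pair drop in case coherence
    noise_sd: float = 1.0
    severity_link: float = 0.4
    alpha: float = 0.05
    n_perm: int = 999
    covariates: tuple = ("age", "sex")
    adjustment: str = "pooled"
    template_path: str | None = None  # None -> the planted pattern written by simulate
    write_reho_maps: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.adjustment not in ("pooled", "controls_only"):
            raise ValueError(f"unknown adjustment {self.adjustment!r}")
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        self.covariates = tuple(self.covariates)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = read_yaml(path)
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["grid_shape"] = list(self.grid_shape)
        d["covariates"] = list(self.covariates)
        if isinstance(d["deficit_coherence_delta"], np.ndarray):
            d["deficit_coherence_delta"] = d["deficit_coherence_delta"].tolist()
        return d


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class DependencyError(RuntimeError):
    """A stage's upstream output is missing."""


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise DependencyError(
            f"stage '{stage}' needs missing input {path.name}; run its upstream stage first"
        )
    return path


def _stage_simulate(cfg: PipelineConfig, out: Path) -> None:
    seed = stage_seed(cfg.seed, "simulate")
    rng = np.random.default_rng(seed)
    atlas = make_toy_atlas(cfg.grid_shape, cfg.n_region_pairs, seed=seed)
    write_atlas(atlas, out / "atlas.nii.gz", out / "regions.tsv")

    P = cfg.n_region_pairs
    delta = cfg.deficit_coherence_delta
    if delta is None:
        delta = rng.uniform(-0.15, -0.02, size=P)  # planted per-pair deficit
    delta = np.broadcast_to(np.asarray(delta, float), (P,)).copy()

    n = cfg.n_cases + cfg.n_controls
    dx = np.concatenate([np.ones(cfg.n_cases, int), np.zeros(cfg.n_controls, int)])
    age = rng.uniform(20.0, 70.0, size=n)
    sex = rng.integers(0, 2, size=n)
    strength = np.where(dx == 1, rng.normal(1.0, 0.3, size=n), 0.0)

    # severity: monotone in the case's pattern strength, plus noise
    severity = np.full(n, np.nan)
    case = dx == 1
    if case.any():
        g = strength[case]
        gs = (g - g.mean()) / g.std() if g.std() > 0 else np.zeros(case.sum())
        link = cfg.severity_link
        severity[case] = 18.0 + 6.0 * (link * gs + np.sqrt(1 - link**2) * rng.normal(size=case.sum()))

    subjects = pd.DataFrame(
        {
            "subject_id": [f"sub-{i + 1:04d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "dx": dx,
            "severity": severity,
        }
    )
    write_tsv(subjects, out / "participants.tsv")

    bold_dir = out / "bold"
    bold_dir.mkdir(exist_ok=True)
    base = np.full(P, cfg.base_coherence)
    for i in range(n):
        coh_pairs = np.clip(base + strength[i] * delta, 0.0, 0.999)
        coh = np.concatenate([coh_pairs, coh_pairs])  # left ids 1..P, right P+1..2P
        vts = simulate_bold(
            atlas, cfg.n_timepoints, coh, noise_sd=cfg.noise_sd,
            seed=int(rng.integers(0, 2**31)),
        )
        write_volume(vts.data, bold_dir / f"{subjects['subject_id'][i]}_bold.nii.gz")

    # the planted deficit direction, on a d-like scale, as the default
    # template (written directly: spin/rvi validate region count themselves)
    write_tsv(
        pd.DataFrame(
            {
                "region": [f"region{j + 1:02d}" for j in range(P)],
                "d": delta / np.abs(delta).max() * 0.5,
            }
        ),
        out / "template_planted.tsv",
    )


def _stage_reho(cfg: PipelineConfig, out: Path) -> None:
    atlas = read_atlas(
        _require(out / "atlas.nii.gz", "reho"), _require(out / "regions.tsv", "reho")
    )
    subjects = read_tsv(_require(out / "participants.tsv", "reho"))
    rows = []
    id_to_col = {
        int(r["region_id"]): f"{r['name']}_{r['hemisphere']}" for _, r in atlas.regions.iterrows()
    }
    for sid in subjects["subject_id"]:
        vts = read_bold(_require(out / "bold" / f"{sid}_bold.nii.gz", "reho"))
        vts.mask &= atlas.mask
        rmap = reho_map(vts)
        if cfg.write_reho_maps:
            write_volume(rmap.values, out / "bold" / f"{sid}_reho.nii.gz")
        means = extract_regional_means(rmap.values, atlas)
        rows.append({id_to_col[rid]: means[rid] for rid in means.index})
    measures = pd.DataFrame(rows)
    table = RegionalMeasureTable(subjects, measures, measure_name="reho")
    bilateral = average_hemispheres(table, atlas.regions)
    write_regional_table(bilateral, out / "regional.tsv")


def _stage_esmap(cfg: PipelineConfig, out: Path) -> None:
    table = read_regional_table(_require(out / "regional.tsv", "esmap"))
    model = DeficitPatternModel(table, covariates=cfg.covariates, adjustment=cfg.adjustment)
    res = model.fit(alpha=cfg.alpha)
    res.to_tsv(out / "esmap.tsv")
    summary = res.summarize()
    summary["ranking"] = [[r, d] for r, d in summary["ranking"]]
    write_json(summary, out / "esmap_summary.json")


def _template_for(cfg: PipelineConfig, out: Path, stage: str) -> TemplateVector:
    path = Path(cfg.template_path) if cfg.template_path else out / "template_planted.tsv"
    return read_template(_require(path, stage))


def _stage_spin(cfg: PipelineConfig, out: Path) -> None:
    es = read_tsv(_require(out / "esmap.tsv", "spin"))
    template = _template_for(cfg, out, "spin")
    regions = read_tsv(_require(out / "regions.tsv", "spin")).rename(columns={"region": "name"})
    left = regions[regions["hemisphere"] == "L"].set_index("name")
    order = list(es["region"])
    cent = left.loc[order, ["cx", "cy", "cz"]].to_numpy(float)
    res = spin_permutation_p(
        es["d"].to_numpy(float),
        template.values[order].to_numpy(float),
        cent,
        n_perm=cfg.n_perm,
        seed=stage_seed(cfg.seed, "spin"),
    )
    write_json(res.as_dict(), out / "spin.json")


def _stage_rvi(cfg: PipelineConfig, out: Path) -> None:
    table = read_regional_table(_require(out / "regional.tsv", "rvi"))
    template = _template_for(cfg, out, "rvi")
    res = RVIModel(
        table, template, covariates=cfg.covariates, adjustment=cfg.adjustment
    ).fit()
    res.to_tsv(out / "rvi.tsv")
    payload = {"group_contrast": res.group_contrast, "symptom_association": res.symptom_association}
    write_json(payload, out / "rvi.json")


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "reho": _stage_reho,
    "esmap": _stage_esmap,
    "spin": _stage_spin,
    "rvi": _stage_rvi,
}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages in dependency order; return the manifest."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    ordered = [s for s in STAGES if s in cfg.stages]
    for stage in ordered:
        _STAGE_FUNCS[stage](cfg, out)

    digests = {
        p.name: _digest(p)
        for p in sorted(out.glob("*"))
        if p.is_file() and p.suffix in (".tsv", ".json", ".gz", ".nii")
        and p.name != "manifest.json"
    }
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "stage_seeds": {s: stage_seed(cfg.seed, s) for s in ordered},
        "stages": ordered,
        "config": cfg.to_dict(),
        "digests": digests,
    }
    write_json(manifest, out / "manifest.json")
    return manifest


def validate_inputs(
    outdir=None,
    atlas_labels=None,
    regions=None,
    regional_table=None,
) -> list:
    """Machine-readable consistency report over pipeline inputs/outputs.

    Each issue is {'severity': 'fatal'|'warning', 'message': str}.  An empty
    list means everything checked out.
    """
    issues: list[dict] = []

    def fatal(msg):
        issues.append({"severity": "fatal", "message": msg})

    if outdir is not None:
        outdir = Path(outdir)
        atlas_labels = atlas_labels or (outdir / "atlas.nii.gz")
        regions = regions or (outdir / "regions.tsv")
        regional_table = regional_table or (outdir / "regional.tsv")

    region_names = None
    if atlas_labels is not None and regions is not None:
        try:
            atlas = read_atlas(atlas_labels, regions)
            region_names = sorted(set(atlas.regions["name"]))
        except FileNotFoundError as e:
            fatal(f"missing file: {e}")
        except ValueError as e:
            fatal(f"atlas inconsistency: {e}")

    if regional_table is not None and Path(regional_table).exists():
        try:
            table = read_regional_table(regional_table)
            if region_names is not None:
                missing = [r for r in region_names if r not in table.measures.columns]
                if missing:
                    fatal(f"regional table lacks atlas regions: {missing}")
            for col in ("age", "sex", "dx"):
                if table.subjects[col].isna().any():
                    fatal(f"covariate column {col!r} has missing values")
            if not set(table.subjects["dx"].unique()) <= {0, 1}:
                fatal("dx must be coded 0 (control) / 1 (case)")
        except ValueError as e:
            fatal(f"regional table invalid: {e}")
    return issues
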