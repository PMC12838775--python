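"""End-to-end orchestration: recordings in, group comparisons out.

The runner executes, per subject: band decomposition -> static low- and
high-order networks per band -> graph metrics -> sliding-window dynamics
(state classification and state entropy per window scheme, band and order)
-> between-frequency networks for every band pair -> supra-adjacency and
cross-band global metrics; then pools all subject-level features into tidy
tables and runs the family-wise group statistics. Every stochastic stage
(K-means restarts) is seeded deterministically from the config seed, so a
re-run with identical config and inputs reproduces every number exactly.
"""

from __future__ import annotations

import itertools
import json
import pathlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import spectral
from .connectivity import (
    ConnectivityMatrix,
    assemble_supra,
    cross_band_global,
    cross_band_lofc,
    hofc,
    lofc,
)
from .dynamics import (
    DEFAULT_PARTITION,
    DEFAULT_SCHEMES,
    Partition,
    WindowScheme,
    classify_states,
    dynamic_networks,
    participation,
    state_entropy,
)
from .graph_metrics import metric_set, prepare_weights
from .group_stats import GroupComparison, compare_cohorts
from .io import matrix_to_csv
from .recording import EEGRecording
from .spectral import BandSpec, DEFAULT_BANDS

__all__ = ["PipelineConfig", "SubjectResult", "ResultsBundle", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything the pipeline needs beyond the recordings themselves."""

    bands: list[BandSpec] = field(default_factory=lambda: list(DEFAULT_BANDS))
    schemes: list[WindowScheme] = field(default_factory=lambda: list(DEFAULT_SCHEMES))
    trim_s: float = 1.0
    filter_order: int = 4
    apply_notch: bool = False
    notch_hz: float = 50.0
    apply_broadband: bool = False
    apply_common_average: bool = False
    partition: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_PARTITION))
    weight_mode: str = "clip"
    pc_features: str = "vector"  # "vector" (node-wise PCs) or "scalar" (network mean)
    kmeans_replicates: int = 50
    stat_variant: str = "pooled"
    q_star: float = 0.05
    include_same_channel_cross: bool = True
    nm_cross_band: bool = False
    run_dynamics: bool = True
    run_cross_band: bool = True
    seed: int = 0

    def validate(self) -> None:
        names = [b.name for b in self.bands]
        if len(set(names)) != len(names):
            raise ValueError("band names must be unique")
        if self.weight_mode not in ("clip", "absolute"):
            raise ValueError("weight_mode must be 'clip' or 'absolute'")
        if self.pc_features not in ("vector", "scalar"):
            raise ValueError("pc_features must be 'vector' or 'scalar'")
        if self.stat_variant not in ("pooled", "welch"):
            raise ValueError("stat_variant must be 'pooled' or 'welch'")
        if not 0 < self.q_star < 1:
            raise ValueError("q_star must lie in (0, 1)")
        Partition(self.partition)  # raises if fewer than 2 modules

    def to_yaml(self) -> str:
        doc = asdict(self)
        doc["bands"] = [{"name": b.name, "f_lo": b.f_lo, "f_hi": b.f_hi} for b in self.bands]
        doc["schemes"] = [
            {"length_s": s.length_s, "overlap_frac": s.overlap_frac} for s in self.schemes
        ]
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        doc = yaml.safe_load(text)
        doc["bands"] = [BandSpec(**b) for b in doc.get("bands", [])] or list(DEFAULT_BANDS)
        doc["schemes"] = [WindowScheme(**s) for s in doc.get("schemes", [])] or list(
            DEFAULT_SCHEMES
        )
        return cls(**doc)


@dataclass
class SubjectResult:
    """All per-subject artifacts of one pipeline run."""

    subject_id: str
    group: str
    static_low: dict[str, ConnectivityMatrix]
    static_high: dict[str, ConnectivityMatrix]
    metrics: dict[tuple[str, str], dict]  # (band, order) -> {cc, cpl, ge, le}
    cross_low: dict[tuple[str, str], ConnectivityMatrix]
    cross_high: dict[tuple[str, str], ConnectivityMatrix]
    global_low: dict  # per-pair + overall off-diagonal-block means
    global_high: dict
    state_entropy: dict[tuple[float, str, str], float]  # (win_s, band, order) -> SE


@dataclass
class ResultsBundle:
    """Cohort-level results: per-subject artifacts, features, comparisons."""

    config: PipelineConfig
    subjects: list[SubjectResult]
    features: pd.DataFrame
    comparisons: list[GroupComparison]

    def comparison(self, family_id: str) -> GroupComparison:
        for c in self.comparisons:
            if c.family_id == family_id:
                return c
        raise KeyError(family_id)

    def write(self, outdir: str | pathlib.Path) -> None:
        """Persist the bundle as labeled CSVs plus a config snapshot."""
        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "config.yaml").write_text(self.config.to_yaml())
        self.features.to_csv(outdir / "features.csv", index=False)
        stats = []
        for comp in self.comparisons:
            t = comp.table.copy()
            t.insert(0, "family", comp.family_id)
            stats.append(t)
        if stats:
            pd.concat(stats, ignore_index=True).to_csv(outdir / "group_stats.csv", index=False)
        mat_dir = outdir / "matrices"
        mat_dir.mkdir(exist_ok=True)
        for sub in self.subjects:
            for band, M in sub.static_low.items():
                matrix_to_csv(M.W, M.node_labels, mat_dir / f"{sub.subject_id}_low_{band}.csv")
            for band, M in sub.static_high.items():
                matrix_to_csv(M.W, M.node_labels, mat_dir / f"{sub.subject_id}_high_{band}.csv")
        summary = {
            "n_subjects": len(self.subjects),
            "groups": sorted({s.group for s in self.subjects}),
            "families": [c.family_id for c in self.comparisons],
        }
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2))


def _edge_items(labels: list[str]):
    for i, j in itertools.combinations(range(len(labels)), 2):
        yield i, j, f"{labels[i]}-{labels[j]}"


def _stage_seed(base: int, *parts: int) -> int:
    return int(np.random.SeedSequence([int(base)] + [int(p) for p in parts]).generate_state(1)[0] % (2**31))


def _cpl_feature(ms) -> float:
    # disconnected networks: fall back to the finite-pair mean so the group
    # test stays defined; the event is flagged in the metric metadata
    return ms.cpl if np.isfinite(ms.cpl) else ms.cpl_finite


def analyze_subject(rec: EEGRecording, config: PipelineConfig, subject_index: int = 0) -> SubjectResult:
    """Run every per-subject stage of the pipeline on one recording."""
    if config.apply_notch:
        rec = spectral.notch(rec, config.notch_hz)
    if config.apply_broadband:
        rec = spectral.broadband(rec)
    if config.apply_common_average:
        rec = spectral.common_average(rec)
    tensors = spectral.decompose(rec, config.bands, trim_s=config.trim_s, order=config.filter_order)
    by_band = {t.band.name: t for t in tensors}
    part = Partition(config.partition)

    static_low = {name: lofc(t) for name, t in by_band.items()}
    static_high = {name: hofc(M) for name, M in static_low.items()}
    metrics = {}
    for name in by_band:
        metrics[(name, "low")] = metric_set(static_low[name], mode=config.weight_mode)
        metrics[(name, "high")] = metric_set(static_high[name], mode=config.weight_mode)

    cross_low: dict[tuple[str, str], ConnectivityMatrix] = {}
    cross_high: dict[tuple[str, str], ConnectivityMatrix] = {}
    global_low: dict = {}
    global_high: dict = {}
    if config.run_cross_band and len(tensors) >= 2:
        for ta, tb in itertools.combinations(tensors, 2):
            ratio = None
            if config.nm_cross_band:
                r = max(1, int(round(tb.band.center / ta.band.center)))
                ratio = (r, 1)
            M = cross_band_lofc(ta, tb, nm_ratio=ratio)
            cross_low[(ta.band.name, tb.band.name)] = M
            cross_high[(ta.band.name, tb.band.name)] = hofc(M)
        supra_low = assemble_supra(list(static_low.values()), list(cross_low.values()))
        per_pair, overall = cross_band_global(supra_low)
        global_low = {"pairs": per_pair, "overall": overall}
        supra_high = assemble_supra(list(static_high.values()), list(cross_high.values()))
        per_pair_h, overall_h = cross_band_global(supra_high)
        global_high = {"pairs": per_pair_h, "overall": overall_h}

    se: dict[tuple[float, str, str], float] = {}
    if config.run_dynamics:
        for s_idx, scheme in enumerate(config.schemes):
            for b_idx, (name, tensor) in enumerate(by_band.items()):
                for o_idx, order in enumerate(("low", "high")):
                    series = dynamic_networks(tensor, scheme, order=order)
                    feats = []
                    for M in series.matrices:
                        W = prepare_weights(M, mode=config.weight_mode)
                        pc, pc_mean = participation(W, part, M.node_labels)
                        feats.append(pc if config.pc_features == "vector" else [pc_mean])
                    seq = classify_states(
                        np.asarray(feats),
                        seed=_stage_seed(config.seed, subject_index, s_idx, b_idx, o_idx),
                        replicates=config.kmeans_replicates,
                        scheme=scheme,
                    )
                    se[(scheme.length_s, name, order)] = state_entropy(seq)

    return SubjectResult(
        subject_id=rec.subject_id,
        group=rec.group,
        static_low=static_low,
        static_high=static_high,
        metrics={k: v.as_dict() | {"cpl_feature": _cpl_feature(v)} for k, v in metrics.items()},
        cross_low=cross_low,
        cross_high=cross_high,
        global_low=global_low,
        global_high=global_high,
        state_entropy=se,
    )


def subject_features(sub: SubjectResult, config: PipelineConfig) -> pd.DataFrame:
    """Tidy per-subject feature rows (family, item, value)."""
    rows = []

    def add(family, item, value):
        rows.append(
            {
                "subject": sub.subject_id,
                "group": sub.group,
                "family": family,
                "item": item,
                "value": float(value),
            }
        )

    for band, M in sub.static_low.items():
        for i, j, item in _edge_items(M.node_labels):
            add(f"edges|{band}|low", item, M.W[i, j])
    for band, M in sub.static_high.items():
        for i, j, item in _edge_items(M.node_labels):
            add(f"edges|{band}|high", item, M.W[i, j])
    for (band, order), ms in sub.metrics.items():
        add(f"metrics|{band}|{order}", "cc", ms["cc"])
        add(f"metrics|{band}|{order}", "cpl", ms["cpl_feature"])
        add(f"metrics|{band}|{order}", "ge", ms["ge"])
        add(f"metrics|{band}|{order}", "le", ms["le"])
    for (ba, bb), M in sub.cross_low.items():
        labels = M.node_labels
        for i in range(len(labels)):
            for j in range(len(labels)):
                if i == j and not config.include_same_channel_cross:
                    continue
                add(f"xedges|{ba}-{bb}|low", f"{labels[i]}>{labels[j]}", M.W[i, j])
    for (ba, bb), M in sub.cross_high.items():
        for i, j, item in _edge_items(M.node_labels):
            add(f"xedges|{ba}-{bb}|high", item, M.W[i, j])
    for order, glob in (("low", sub.global_low), ("high", sub.global_high)):
        if glob:
            for (ba, bb), v in glob["pairs"].items():
                add(f"xglobal|{order}", f"{ba}-{bb}", v)
            add(f"xglobal|{order}", "overall", glob["overall"])
    for (win, band, order), v in sub.state_entropy.items():
        add(f"se|{band}|{order}", f"win{win:g}s", v)
    return pd.DataFrame(rows)


def run_pipeline(
    recordings: list[EEGRecording],
    config: PipelineConfig | None = None,
) -> ResultsBundle:
    """Run the full analysis on a cohort of recordings.

    Group comparisons are produced when the cohort carries exactly two group
    labels; a single-group cohort yields an empty comparison list.
    """
    config = config or PipelineConfig()
    config.validate()
    subjects = []
    frames = []
    for idx, rec in enumerate(recordings):
        try:
            sub = analyze_subject(rec, config, subject_index=idx)
        except Exception as exc:
            raise RuntimeError(
                f"pipeline failed for subject {rec.subject_id!r}: {exc}"
            ) from exc
        subjects.append(sub)
        frames.append(subject_features(sub, config))
    features = pd.concat(frames, ignore_index=True)
    groups = sorted({s.group for s in subjects if s.group})
    comparisons: list[GroupComparison] = []
    if len(groups) == 2:
        comparisons = compare_cohorts(
            features, groups[0], groups[1],
            q_star=config.q_star, variant=config.stat_variant,
        )
    return ResultsBundle(
        config=config, subjects=subjects, features=features, comparisons=comparisons
    )
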