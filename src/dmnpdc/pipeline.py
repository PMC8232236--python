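"""End-to-end pipeline: generate -> preprocess -> connect -> stats.

A single :class:`PipelineConfig` (optionally loaded from YAML) drives the
whole run deterministically: the master seed fans out to per-subject,
per-stage seeds, so repeated runs are byte-identical and enlarging the
cohort does not perturb existing subjects.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import band_power as bp
from . import group_stats as gs
from .pdc import DEFAULT_BANDS, ConnectivityTensor, subject_connectivity
from .preprocessing import preprocess
from .synthetic import GROUPS, CohortDataset, make_cohort, save_cohort

__all__ = ["PipelineConfig", "run_pipeline", "export_heatmaps"]

log = logging.getLogger("dmnpdc")


@dataclass
class PipelineConfig:
    seed: int = 0
    n_per_group: int = 22
    fs_raw: float = 256.0  # set 2048 to exercise the downsampling path
    fs_work: float = 256.0
    duration_s: float = 180.0
    band_low: float = 0.4
    band_high: float = 50.0
    epoch_len_s: float = 4.0
    z_thresh: float = 5.0
    abs_thresh: float = float("inf")
    apply_car: bool = False
    apply_bandpass: bool = False  # see docs/methods.md: filtering biases VAR fits
    order_policy: str = "aic"  # "aic" or an integer as string
    p_min: int = 1
    p_max: int = 12
    pdc_squared: bool = False
    anova_layout: str = "connection"  # "connection" | "subject"
    line_noise: float = 0.0
    out_dir: str = "results/pipeline"
    save_recordings: bool = False
    save_figures: bool = False

    def validate(self) -> None:
        if self.n_per_group < 3:
            raise ValueError("n_per_group must be >= 3")
        if not (0 < self.band_low < self.band_high < self.fs_work / 2):
            raise ValueError("band edges must satisfy 0 < low < high < fs/2")
        if self.fs_raw % self.fs_work:
            raise ValueError("fs_raw must be an integer multiple of fs_work")
        if self.duration_s < 8:
            raise ValueError("duration_s must be >= 8")
        for b in DEFAULT_BANDS.bands:
            if b.hi > self.fs_work / 2:
                raise ValueError(f"band {b.name} exceeds the working Nyquist")
        if self.anova_layout not in ("connection", "subject"):
            raise ValueError("anova_layout must be 'connection' or 'subject'")
        if self.order_policy != "aic":
            int(self.order_policy)  # raises if not an integer

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _order_policy(cfg: PipelineConfig):
    return "aic" if cfg.order_policy == "aic" else int(cfg.order_policy)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full pipeline and write manifest, connectivity tables, the
    statistics report and the group heat-map matrices under ``cfg.out_dir``.

    Returns a results bundle with the cohort, per-subject tensors and the
    statistics report.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    # --- generate -----------------------------------------------------
    cohort = make_cohort(
        n_per_group=cfg.n_per_group,
        fs=cfg.fs_raw,
        duration_s=cfg.duration_s,
        seed=cfg.seed,
        line_noise=cfg.line_noise,
    )
    cohort.manifest().to_csv(out / "manifest.csv", index=False)
    if cfg.save_recordings:
        save_cohort(cohort, out / "recordings")
    log.info("generate: %d subjects in %.1fs", len(cohort.subjects), time.time() - t0)

    # --- preprocess + connect -----------------------------------------
    tensors: dict[str, ConnectivityTensor] = {}
    power_rows = []
    for subj in cohort.subjects:
        try:
            epochs = preprocess(
                subj.recording,
                low=cfg.band_low,
                high=cfg.band_high,
                target_fs=cfg.fs_work,
                epoch_len_s=cfg.epoch_len_s,
                z_thresh=cfg.z_thresh,
                abs_thresh=cfg.abs_thresh,
                apply_car=cfg.apply_car,
                apply_bandpass=cfg.apply_bandpass,
            )
            tensors[subj.id] = subject_connectivity(
                epochs,
                order_policy=_order_policy(cfg),
                squared=cfg.pdc_squared,
                subject_id=subj.id,
                p_range=(cfg.p_min, cfg.p_max),
            )
            freqs, psd = bp.welch_psd(epochs)
            tab = bp.absolute_band_power(freqs, psd, labels=epochs.labels)
            tab.insert(0, "subject_id", subj.id)
            power_rows.append(tab)
        except Exception as exc:  # annotate with stage context
            raise RuntimeError(f"connect stage failed for {subj.id}") from exc

    _write_long_csv(tensors, cohort, out / "connectivity.csv")
    pd.concat(power_rows, ignore_index=True).to_csv(
        out / "band_power.csv", index=False
    )
    log.info("connect: done at %.1fs", time.time() - t0)

    # --- stats ---------------------------------------------------------
    report = compute_stats(cohort, tensors, layout=cfg.anova_layout)
    report["config"] = asdict(cfg)
    with open(out / "stats.json", "w") as fh:
        json.dump(report, fh, indent=2)

    # --- heat-maps -----------------------------------------------------
    by_group = _tensors_by_group(cohort, tensors)
    export_heatmaps(by_group, out / "heatmaps", figures=cfg.save_figures)
    log.info("pipeline complete in %.1fs", time.time() - t0)
    return {"cohort": cohort, "tensors": tensors, "report": report}


def _tensors_by_group(cohort: CohortDataset, tensors: dict) -> dict:
    return {
        g: [tensors[s.id] for s in cohort.group_subjects(g) if s.id in tensors]
        for g in GROUPS
    }


def _write_long_csv(tensors: dict, cohort: CohortDataset, path: Path) -> None:
    labels = cohort.montage.labels
    rows = []
    for sid, t in tensors.items():
        for b, band in enumerate(t.band_names):
            for i, sink in enumerate(labels):
                for j, source in enumerate(labels):
                    rows.append(
                        (sid, band, source, sink, t.values[i, j, b])
                    )
    pd.DataFrame(
        rows, columns=["subject_id", "band", "source", "sink", "pdc"]
    ).to_csv(path, index=False)


def compute_stats(
    cohort: CohortDataset, tensors: dict, layout: str = "connection"
) -> dict:
    """Band-wise group ANOVA (+ Tukey HSD, Bonferroni across bands), group
    summaries, normality screens, and PDC-SIAS Pearson correlations."""
    by_group = _tensors_by_group(cohort, tensors)
    report: dict = {"layout": layout, "bands": {}, "correlations": {}}
    pvals = []
    for band in DEFAULT_BANDS.names:
        subject_vals = gs.subject_level_values(by_group, band)
        vals = (
            gs.connection_level_values(by_group, band)
            if layout == "connection"
            else subject_vals
        )
        groups = [vals[g] for g in GROUPS]
        res = gs.oneway_anova(groups)
        tuk = gs.tukey_hsd(groups, labels=list(GROUPS))
        normality = {}
        for g in GROUPS:
            try:
                stat, p = gs.ks_normality(subject_vals[g])
                normality[g] = {"stat": stat, "p": p}
            except ValueError:
                normality[g] = {"stat": None, "p": None}
        report["bands"][band] = {
            "anova": asdict(res),
            "tukey": tuk.to_dict(orient="records"),
            "normality_ks": normality,
            "group_summary": gs.group_summary(by_group, band).to_dict(
                orient="records"
            ),
        }
        pvals.append(res.p)
    report["bonferroni_reject_bands"] = dict(
        zip(DEFAULT_BANDS.names, map(bool, gs.bonferroni(pvals)))
    )

    # alpha-band PDC vs SIAS, per group and pooled
    for g in GROUPS:
        subs = cohort.group_subjects(g)
        alpha = [tensors[s.id].mean_offdiag("alpha") for s in subs]
        sias = [s.sias for s in subs]
        c = gs.pearson_corr(alpha, sias)
        report["correlations"][g] = asdict(c)
    alpha_all = [tensors[s.id].mean_offdiag("alpha") for s in cohort.subjects]
    sias_all = [s.sias for s in cohort.subjects]
    report["correlations"]["pooled"] = asdict(gs.pearson_corr(alpha_all, sias_all))
    return report


def export_heatmaps(
    tensors_by_group: dict,
    out_dir: str | Path,
    bands: tuple[str, ...] | None = None,
    figures: bool = False,
) -> list[Path]:
    """Write the group-mean 8x8 connectivity matrix (diagonal zero) per
    group x band as CSV, optionally with a PNG heat-map."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for g, tensors in tensors_by_group.items():
        if not tensors:
            raise ValueError(f"empty group: {g}")
        labels = list(tensors[0].labels) or [
            str(i) for i in range(tensors[0].values.shape[0])
        ]
        band_names = bands or tensors[0].band_names
        for band in band_names:
            mat = np.mean([t.band(band) for t in tensors], axis=0)
            df = pd.DataFrame(mat, index=labels, columns=labels)
            path = out_dir / f"{g}_{band}.csv"
            df.to_csv(path)
            written.append(path)
            if figures:
                _heatmap_png(mat, labels, g, band, path.with_suffix(".png"))
    return written


def _heatmap_png(mat, labels, group, band, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4))
    im = ax.imshow(mat, cmap="jet", vmin=0, vmax=mat.max() or 1)
    ax.set_xticks(range(len(labels)), labels, rotation=45)
    ax.set_yticks(range(len(labels)), labels)
    ax.set_xlabel("source")
    ax.set_ylabel("sink")
    ax.set_title(f"{group} — {band} (mean PDC)")
    fig.colorbar(im, ax=ax, label=f"PDC [{mat.min():.3f}, {mat.max():.3f}]")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
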