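"""Cohort pipeline: simulate -> analyze -> compare.

Thin orchestration over the library modules.  A *cohort bundle* directory
(produced by :func:`run_simulate` or arranged by hand) holds per-subject
recording CSVs, event sidecars, Racine CSVs and a ``manifest.json``.
:func:`run_analyze` standardizes each recording, detects onsets and writes
tidy feature tables; :func:`run_compare` runs the group statistics and
writes a JSON + human-readable report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior, connectivity, features, group_stats, io_eeg, spectral
from .errors import DegenerateSignalError, PreconditionError, SeizdynError
from .synthetic_data import (
    CohortConfig,
    default_cohorts,
    generate_cohorts,
    generate_subject,
)

log = logging.getLogger("seizdyn")

#: Channels analyzed per role family (one cortical, one hippocampal, as in
#: the per-panel cortex/hippocampus split of the cohort comparison).
DEFAULT_CHANNELS = ("cortical_left", "hippocampal_1")

DEFAULT_PAIRS = (
    ("cortical_left", "cortical_right"),
    ("cortical_left", "hippocampal_1"),
    ("hippocampal_1", "hippocampal_2"),
)


def load_cohort_configs(config_path: str | Path | None) -> list[CohortConfig]:
    """Cohort configs from a YAML file, or the calibrated default groups."""
    if config_path is None:
        return default_cohorts()
    with open(config_path) as fh:
        doc = yaml.safe_load(fh)
    return [CohortConfig.from_dict(d) for d in doc["groups"]]


def run_simulate(
    out_dir: str | Path,
    config_path: str | Path | None = None,
    seed: int | None = 0,
) -> dict:
    cfgs = load_cohort_configs(config_path)
    return generate_cohorts(cfgs, out_dir, seed=seed)


def _iter_manifest_subjects(cohort_dir: Path):
    manifest = json.loads((cohort_dir / "manifest.json").read_text())
    for group, entry in manifest["groups"].items():
        for sub in entry["subjects"]:
            yield group, sub


def run_analyze(
    cohort_dir: str | Path,
    out_dir: str | Path,
    channels: tuple[str, ...] = DEFAULT_CHANNELS,
    pairs: tuple[tuple[str, str], ...] = DEFAULT_PAIRS,
    onset_channel: str = "hippocampal_1",
    with_connectivity: bool = True,
    with_spectrograms: bool = False,
) -> dict:
    """Extract per-subject features for every recording in a cohort bundle.

    Emits tidy tables into ``out_dir``: ``onsets.csv``, ``llcum.csv``,
    ``line_length.csv``, ``highgamma.csv`` and ``connectivity.csv``.
    Subjects that fail a stage (missing channel, no detectable onset,
    degenerate signal) are skipped for that stage and logged in
    ``analysis_log.json``; the run continues.
    """
    cohort_dir, out_dir = Path(cohort_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    onsets, ll_rows, llcum_rows, hg_rows, conn_rows, failures = [], [], [], [], [], []

    for group, sub in _iter_manifest_subjects(cohort_dir):
        sid = sub["subject_id"]
        rec = io_eeg.load_recording(
            cohort_dir / sub["recording"], fs=sub["fs"], subject_id=sid, group=group
        )
        rec = io_eeg.relative_time(io_eeg.standardize(rec))

        try:
            onset = features.detect_onset(rec, onset_channel)
        except (SeizdynError, KeyError) as exc:
            failures.append({"subject": sid, "stage": "onset", "error": str(exc)})
            onset = None
        onsets.append({"subject_id": sid, "group": group, "onset_s": onset})

        for ch in channels:
            try:
                wll = features.windowed_line_length(rec, ch)
            except (SeizdynError, KeyError) as exc:
                failures.append({"subject": sid, "stage": f"ll:{ch}", "error": str(exc)})
                continue
            ll_rows.append(
                pd.DataFrame(
                    {
                        "subject_id": sid,
                        "group": group,
                        "channel": ch,
                        "time_s": wll.times,
                        "value": wll.values,
                    }
                )
            )
            if onset is None:
                continue
            try:
                curve = features.cumulative_line_length(rec, ch, onset)
            except (SeizdynError, KeyError) as exc:
                failures.append(
                    {"subject": sid, "stage": f"llcum:{ch}", "error": str(exc)}
                )
                continue
            llcum_rows.append(
                pd.DataFrame(
                    {
                        "subject_id": sid,
                        "group": group,
                        "channel": ch,
                        "time_s": curve.times,
                        "value": curve.values,
                        "truncated": curve.truncated,
                    }
                )
            )

        light_ons = rec.events.times("light_on")
        if light_ons.size:
            for pi, on in enumerate(light_ons):
                try:
                    series = spectral.normalized_high_gamma(
                        rec, onset_channel, float(on)
                    )
                except (SeizdynError, KeyError) as exc:
                    failures.append(
                        {"subject": sid, "stage": f"hg:{pi}", "error": str(exc)}
                    )
                    continue
                hg_rows.append(
                    pd.DataFrame(
                        {
                            "subject_id": sid,
                            "group": group,
                            "pulse_index": pi,
                            "bin_start_s": series.bin_starts,
                            "power": series.power,
                            "normalized": series.normalized,
                        }
                    )
                )
        else:
            log.info("subject %s has no light events; high-gamma stage skipped", sid)
            failures.append(
                {"subject": sid, "stage": "hg", "error": "no light events (skipped)"}
            )

        if with_connectivity:
            for pair in pairs:
                try:
                    ps = connectivity.phase_synchrony(rec, pair)
                    xs = connectivity.cross_correlation(rec, pair)
                except (SeizdynError, KeyError) as exc:
                    failures.append(
                        {"subject": sid, "stage": f"conn:{pair}", "error": str(exc)}
                    )
                    continue
                conn_rows.append(
                    pd.DataFrame(
                        {
                            "subject_id": sid,
                            "group": group,
                            "pair": f"{pair[0]}|{pair[1]}",
                            "time_s": ps.times,
                            "plv": ps.plv,
                            "xcorr": xs.xcorr,
                        }
                    )
                )

        if with_spectrograms:
            for ch in channels:
                spec = features.spectrogram(rec, ch)
                keep = spec.freqs <= 50.0
                df = pd.DataFrame(spec.power[keep].T, columns=spec.freqs[keep])
                df.insert(0, "time_s", spec.times)
                df.to_csv(out_dir / f"spectrogram_{sid}_{ch}.csv", index=False)

    def _dump(rows, name):
        if rows:
            pd.concat(rows, ignore_index=True).to_csv(out_dir / name, index=False)

    pd.DataFrame(onsets).to_csv(out_dir / "onsets.csv", index=False)
    _dump(ll_rows, "line_length.csv")
    _dump(llcum_rows, "llcum.csv")
    _dump(hg_rows, "highgamma.csv")
    _dump(conn_rows, "connectivity.csv")
    (out_dir / "analysis_log.json").write_text(json.dumps(failures, indent=1))
    return {"out_dir": str(out_dir), "failures": failures}


def simulate_detected_onsets(
    cfg: CohortConfig,
    n_subjects: int | None = None,
    onset_channel: str = "hippocampal_1",
    post_onset_min: float = 2.5,
) -> np.ndarray:
    """Generate a cohort in memory and return detected onsets (minutes).

    Recordings are truncated shortly after the seizure starts, which leaves
    onset detection unaffected; subjects whose onset is not detected yield
    NaN.
    """
    cfg = dataclasses.replace(cfg, post_onset_min=post_onset_min)
    n = cfg.n_subjects if n_subjects is None else n_subjects
    out = []
    for i in range(n):
        rec, _, _ = generate_subject(cfg, i)
        rec = io_eeg.relative_time(io_eeg.standardize(rec))
        det = features.detect_onset(rec, onset_channel)
        out.append(np.nan if det is None else det / 60.0)
    return np.array(out)


def simulate_llcum_cohort(
    cfg: CohortConfig,
    n_subjects: int | None = None,
    channel: str = "cortical_left",
    onset_channel: str = "hippocampal_1",
) -> np.ndarray:
    """Full-waveform cohort: per-subject cumulative line-length curves.

    Each subject is generated, standardized, its onset detected from
    windowed line length, and the normalized cumulative line-length curve
    computed for 25 min from the detected onset (ground-truth onset as a
    fallback if detection fails).  Returns a (subjects x 1501) matrix on
    the common 1 s grid.
    """
    n = cfg.n_subjects if n_subjects is None else n_subjects
    rows = []
    for i in range(n):
        rec, _, profile = generate_subject(cfg, i)
        rec = io_eeg.relative_time(io_eeg.standardize(rec))
        onset = features.detect_onset(rec, onset_channel)
        if onset is None:
            onset = profile.onset_s
        rows.append(features.cumulative_line_length(rec, channel, onset).values)
    return np.vstack(rows)


def _curve_matrix(df: pd.DataFrame, channel: str, groups: list[str]):
    sel = df[(df["channel"] == channel) & df["group"].isin(groups)]
    if sel.empty:
        return None, None
    pivot = sel.pivot_table(index="subject_id", columns="time_s", values="value")
    return pivot.to_numpy(), pivot.columns.to_numpy(dtype=float)


def run_compare(
    cohort_dir: str | Path,
    features_dir: str | Path,
    out_dir: str | Path,
    control_group: str = "sham_control",
    experimental_group: str = "experimental",
    alpha_point: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    channels: tuple[str, ...] = DEFAULT_CHANNELS,
) -> dict:
    """Group statistics: onset ANOVA + Holm-Sidak, cluster tests, report."""
    cohort_dir, features_dir = Path(cohort_dir), Path(features_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    onsets = pd.read_csv(features_dir / "onsets.csv").dropna(subset=["onset_s"])
    groups = sorted(onsets["group"].unique())
    if len(groups) < 2:
        raise PreconditionError("need >= 2 groups with detected onsets")
    by_group = {
        g: onsets.loc[onsets["group"] == g, "onset_s"].to_numpy() / 60.0
        for g in groups
    }
    report: dict = {"seed": seed, "n_perm": n_perm, "alpha_point": alpha_point}

    usable = {g: v for g, v in by_group.items() if v.size >= 2}
    F, p = group_stats.anova_oneway(list(usable.values()))
    others = [g for g in usable if g != control_group]
    from scipy import stats as sps

    raw = [
        float(sps.ttest_ind(usable[g], usable[control_group]).pvalue) for g in others
    ]
    adj = group_stats.holm_sidak_vs_control(raw, others) if others else []
    report["onset_anova"] = {
        "F": F,
        "p": p,
        "group_means_min": {g: float(v.mean()) for g, v in usable.items()},
        "group_n": {g: int(v.size) for g, v in usable.items()},
        "vs_control": {
            g: {"p_raw": pr, "p_holm_sidak": float(pa)}
            for g, pr, pa in zip(others, raw, adj)
        },
    }

    control_pool = [g for g in groups if g != experimental_group]
    report["llcum_clusters"] = {}
    llcum_path = features_dir / "llcum.csv"
    if llcum_path.exists():
        df = pd.read_csv(llcum_path)
        for ch in channels:
            ctrl, times = _curve_matrix(df, ch, control_pool)
            expe, _ = _curve_matrix(df, ch, [experimental_group])
            if ctrl is None or expe is None:
                continue
            res = group_stats.cluster_permutation_test(
                ctrl, expe, stat="t", alpha_point=alpha_point,
                n_perm=n_perm, seed=seed, times=times,
            )
            report["llcum_clusters"][ch] = res.to_dict()

    racine_series = []
    for group, sub in _iter_manifest_subjects(cohort_dir):
        rpath = cohort_dir / sub.get("racine", "")
        if rpath.is_file():
            racine_series.append(
                behavior.load_racine(rpath, subject_id=sub["subject_id"], group=group)
            )
    if racine_series:
        curves = behavior.group_racine_curves(racine_series)
        ctrl_rows = [
            curves.matrices[g] for g in control_pool if g in curves.matrices
        ]
        if ctrl_rows and experimental_group in curves.matrices:
            A = np.vstack(ctrl_rows)
            B = curves.matrices[experimental_group]
            try:
                res = behavior.compare_racine(
                    A, B, alpha_point=alpha_point, n_perm=n_perm,
                    seed=seed, times=curves.epoch_starts,
                )
                report["racine_clusters"] = res.to_dict()
            except (PreconditionError, DegenerateSignalError) as exc:
                report["racine_clusters"] = {"error": str(exc)}

    (out_dir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    (out_dir / "report.txt").write_text(_format_report(report))
    return report


def _format_report(report: dict) -> str:
    lines = ["seizdyn group comparison report", "=" * 34]
    a = report.get("onset_anova", {})
    if a:
        lines.append(
            f"Onset one-way ANOVA: F = {a['F']:.3f}, p = {a['p']:.4f}"
        )
        for g, m in a["group_means_min"].items():
            lines.append(f"  {g}: mean onset {m:.1f} min (n = {a['group_n'][g]})")
        for g, d in a.get("vs_control", {}).items():
            lines.append(
                f"  {g} vs control: p = {d['p_raw']:.4f}"
                f" (Holm-Sidak {d['p_holm_sidak']:.4f})"
            )
    for ch, d in report.get("llcum_clusters", {}).items():
        sig = [c for c in d["clusters"] if c["p"] < 0.05]
        lines.append(
            f"LL_cum clusters [{ch}]: {len(d['clusters'])} found,"
            f" {len(sig)} significant at p<0.05"
        )
        for c in sig:
            lines.append(
                f"  {c['start_s']:.0f}-{c['end_s']:.0f} s, mass {c['mass']:.1f},"
                f" p = {c['p']:.4f}"
            )
    d = report.get("racine_clusters")
    if isinstance(d, dict) and "clusters" in d:
        sig = [c for c in d["clusters"] if c["p"] < 0.05]
        lines.append(
            f"Racine clusters: {len(d['clusters'])} found, {len(sig)} significant"
        )
        for c in sig:
            lines.append(
                f"  {c['start_s']:.0f}-{c['end_s']:.0f} s, p = {c['p']:.4f}"
            )
    return "\n".join(lines) + "\n"
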