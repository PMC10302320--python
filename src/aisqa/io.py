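"""Readers/writers, run configuration and the end-to-end batch pipeline.

Recordings are interchanged as plain CSV (``time_s,amplitude_mv`` with a
header row, '.' decimal, UTF-8); ground truth travels as a JSON sidecar.
Every batch output embeds a provenance block (config hash, seed, package
version) so results are attributable to an exact parameterization.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .features import FEATURE_NAMES, HeartRateGateError, extract_features
from .model import AISQAModel, SplitSpec, predict_aisqa, train
from .morphology import PrototypeSet, TooFewBeatsError, fit_prototypes
from .preprocessing import (
    ECGRecording,
    PeakDetectionError,
    SegmentTooShortError,
    TooShortError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "ParseError",
    "read_recording",
    "write_recording",
    "read_ground_truth_sidecar",
    "write_ground_truth_sidecar",
    "default_prototypes",
    "run_pipeline",
    "write_prototypes",
    "read_prototypes",
]


class ParseError(ValueError):
    """A recording file does not follow the expected CSV dialect."""


@dataclass
class RunConfig:
    """All tunable pipeline parameters with their study defaults."""

    fs: float = 200.0
    window_len_s: float = 5.0
    cc_thr: float = 0.982
    n_top: int = 5
    hr_bounds_bpm: tuple = (40.0, 150.0)
    n_points: int = 200
    k_clusters: int = 4
    coverage_target: float = 0.90
    dtw_band: float = 0.10
    kernel: str = "exponential"
    holdout_fraction: float = 0.2
    cv_folds: int = 5
    seed: int = 0
    resample_on_fs_mismatch: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def provenance(self) -> dict:
        return {"config_hash": self.hash(), "seed": self.seed, "version": __version__}


def read_recording(
    path: str | Path, expected_fs: float = 200.0, resample: bool = False
) -> ECGRecording:
    """Read a ``time_s,amplitude_mv`` CSV into an ECGRecording.

    A sampling-rate mismatch is rejected by default; with ``resample=True``
    the trace is polyphase-resampled to ``expected_fs``.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip()
    if header.split(",")[:2] != ["time_s", "amplitude_mv"]:
        raise ParseError(f"{path}:1: expected header 'time_s,amplitude_mv'")
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pandas reports the offending line itself
        raise ParseError(f"{path}: {exc}") from exc
    t = df["time_s"].to_numpy(dtype=float)
    x = df["amplitude_mv"].to_numpy(dtype=float)
    if t.size < 2:
        raise ParseError(f"{path}: need at least 2 samples")
    fs = 1.0 / float(np.median(np.diff(t)))
    if not np.isclose(fs, expected_fs, rtol=1e-3):
        if not resample:
            raise ParseError(
                f"{path}: sampling rate {fs:.1f} Hz != expected {expected_fs:.1f} Hz"
            )
        from scipy.signal import resample_poly
        from fractions import Fraction

        frac = Fraction(expected_fs / fs).limit_denominator(1000)
        x = resample_poly(x, frac.numerator, frac.denominator)
        fs = expected_fs
    return ECGRecording(samples=x, fs=fs, id=path.stem)


def write_recording(rec: ECGRecording, path: str | Path) -> None:
    """Write a recording as full-precision ``time_s,amplitude_mv`` CSV."""
    t = np.arange(rec.samples.size) / rec.fs
    df = pd.DataFrame({"time_s": t, "amplitude_mv": rec.samples})
    df.to_csv(path, index=False, float_format="%.17g")


def write_ground_truth_sidecar(truth, path: str | Path) -> None:
    payload = {
        "r_peaks": truth.r_peaks.tolist(),
        "artifact_windows": [list(w) for w in truth.artifact_windows],
        "quality_label": int(truth.quality_label),
        "rhythm": truth.rhythm,
        "inverted": bool(truth.inverted),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth_sidecar(path: str | Path):
    from .synthetic_ecg import GroundTruth

    data = json.loads(Path(path).read_text())
    return GroundTruth(
        r_peaks=np.asarray(data["r_peaks"], dtype=int),
        artifact_windows=[tuple(w) for w in data["artifact_windows"]],
        quality_label=int(data["quality_label"]),
        rhythm=data["rhythm"],
        inverted=bool(data["inverted"]),
    )


def write_prototypes(pset: PrototypeSet, csv_path: str | Path) -> None:
    """Persist prototypes as CSV (cycle_pct, mean_k, std_k) + JSON manifest."""
    n = len(pset.clusters[0].mean)
    cols = {"cycle_pct": np.arange(n) / n * 100.0}
    for i, c in enumerate(pset.clusters):
        cols[f"mean_{i}"] = c.mean
        cols[f"std_{i}"] = c.std
    pd.DataFrame(cols).to_csv(csv_path, index=False, float_format="%.17g")
    manifest = {
        "k": pset.k,
        "seed": pset.seed,
        "coverage_target": pset.coverage_target,
        "selected": pset.selected,
        "fractions": [c.fraction for c in pset.clusters],
    }
    Path(csv_path).with_suffix(".json").write_text(json.dumps(manifest, indent=1))


def read_prototypes(csv_path: str | Path) -> PrototypeSet:
    from .morphology import PrototypeCluster

    df = pd.read_csv(csv_path)
    manifest = json.loads(Path(csv_path).with_suffix(".json").read_text())
    clusters = []
    for i in range(manifest["k"]):
        clusters.append(
            PrototypeCluster(
                mean=df[f"mean_{i}"].to_numpy(),
                std=df[f"std_{i}"].to_numpy(),
                fraction=manifest["fractions"][i],
                members=np.array([], dtype=int),
            )
        )
    return PrototypeSet(
        clusters=clusters,
        selected=list(manifest["selected"]),
        k=manifest["k"],
        seed=manifest["seed"],
        coverage_target=manifest["coverage_target"],
    )


def default_prototypes(seed: int = 0, n_recordings: int = 30) -> PrototypeSet:
    """Ideal prototypes fitted to generated excellent normal-sinus recordings."""
    from .synthetic_ecg import SyntheticConfig, synthesize_recording

    rng = np.random.default_rng(seed)
    recs = []
    for _ in range(n_recordings):
        cfg = SyntheticConfig(
            rhythm="NSR",
            mean_hr=float(rng.uniform(55, 95)),
            snr_db=float(rng.uniform(22, 30)),
            seed=int(rng.integers(2**31)),
        )
        recs.append(synthesize_recording(cfg)[0])
    return fit_prototypes(recs, seed=seed)


_FAILURE_REASONS = {
    TooShortError: "too_short",
    SegmentTooShortError: "invalid_no_30s_segment",
    PeakDetectionError: "peak_detection_failed",
    HeartRateGateError: "hr_out_of_range",
    TooFewBeatsError: "too_few_beats",
}


def run_pipeline(
    recordings: list[ECGRecording],
    config: RunConfig | None = None,
    prototypes: PrototypeSet | None = None,
    model: AISQAModel | None = None,
) -> dict:
    """Preprocess, extract features and score a batch of recordings.

    Per-recording failures (too-short segment, peak failure, heart-rate
    gate) are recorded with reason codes and never abort the batch.  When no
    prototype set is supplied it is fitted from the batch's excellent
    normal-rhythm recordings (falling back to synthetic defaults), and when
    no model is supplied one is trained on the batch's labelled recordings
    if there are enough of them.

    Returns ``{"table": DataFrame, "summary": dict, "provenance": dict,
    "model": AISQAModel | None, "prototypes": PrototypeSet}``.
    """
    if not recordings:
        raise ValueError("need at least one recording")
    config = config or RunConfig()
    if prototypes is None:
        donors = [
            r
            for r in recordings
            if r.expert_label == 0 and r.device_decision != "AF"
        ]
        if len(donors) >= config.k_clusters + 2:
            prototypes = fit_prototypes(
                donors, k=config.k_clusters, seed=config.seed, n_points=config.n_points
            )
        else:
            logger.info("too few excellent recordings in batch; synthetic prototypes")
            prototypes = default_prototypes(seed=config.seed)

    rows = []
    for rec in recordings:
        row: dict = {"id": rec.id, "status": "valid", "reason": ""}
        try:
            fv = extract_features(rec, prototypes)
            row.update(fv.as_dict())
        except tuple(_FAILURE_REASONS) as exc:
            row["status"] = "invalid"
            row["reason"] = _FAILURE_REASONS[type(exc)]
        if rec.expert_label is not None:
            row["expert_label"] = rec.expert_label
        if rec.device_decision is not None:
            row["device_decision"] = rec.device_decision
        rows.append(row)
    table = pd.DataFrame(rows)

    valid = table["status"] == "valid"
    if model is None and "expert_label" in table.columns:
        labelled = valid & table["expert_label"].notna()
        if labelled.sum() >= 25:
            model = train(
                table.loc[labelled, list(FEATURE_NAMES)].to_numpy(),
                table.loc[labelled, "expert_label"].to_numpy(dtype=float),
                kernel=config.kernel,
                spec=SplitSpec(
                    holdout_fraction=config.holdout_fraction,
                    cv_folds=config.cv_folds,
                    seed=config.seed,
                ),
            )
    if model is not None and valid.any():
        scores = predict_aisqa(model, table.loc[valid, list(FEATURE_NAMES)].to_numpy())
        table.loc[valid, "aisqa"] = scores

    summary = {
        "total": len(table),
        "valid": int(valid.sum()),
        "invalid": int((~valid).sum()),
        "reasons": table.loc[~valid, "reason"].value_counts().to_dict(),
    }
    if summary["valid"] + summary["invalid"] != summary["total"]:
        raise AssertionError("summary counts must partition the input")
    return {
        "table": table,
        "summary": summary,
        "provenance": config.provenance(),
        "model": model,
        "prototypes": prototypes,
    }
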