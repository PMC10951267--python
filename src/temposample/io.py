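"""Serialization: trial logs as CSV, run configuration as JSON, seed splitting.

The trial-log dialect is a plain CSV with a header; the 24 SNR values of a
trial are stored in one column as semicolon-separated ``repr`` floats, which
round-trips bit-exactly through text. Every output carries a
``schema_version`` marker.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .experiment import LOG_COLUMNS
from .stimuli import FRAME_RATE, N_FRAMES, SNR_FREQS, SNR_MAX

__all__ = ["RunConfig", "write_trial_log", "read_trial_log", "stage_seed", "SCHEMA_VERSION"]

SCHEMA_VERSION = 1

#: Named pipeline stages; each gets its own child seed of the master seed.
STAGES = ("schedule", "observer", "experiment", "ci", "classifier")


def stage_seed(master_seed: int, stage: str, index: int = 0) -> int:
    """Derive a per-stage integer seed from the master seed.

    Splitting rule: ``SeedSequence((master_seed, stage_rank, index))`` where
    ``stage_rank`` is the stage's position in :data:`STAGES`; the first word
    of its state, reduced below 2**31, is the stage seed.
    """
    rank = STAGES.index(stage)
    ss = np.random.SeedSequence((int(master_seed), rank, int(index)))
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass
class RunConfig:
    """All pipeline parameters with their defaults, JSON round-trippable."""

    frame_rate: float = FRAME_RATE
    duration_ms: float = 1000.0 * N_FRAMES / FRAME_RATE
    snr_freqs: tuple = SNR_FREQS
    snr_max: float = SNR_MAX
    filter_order: int = 2
    px_per_deg: float = 32.0
    noise: str = "uniform"
    n_participants: int = 4
    n_words: int = 100
    n_sessions: int = 4
    blocks_per_session: int = 2
    trials_per_block: int = 100
    n_boot: int = 500
    n_perm: int = 500
    alpha: float = 0.05
    fwhm_time_ms: float = 19.6
    fwhm_tf_time_ms: float = 29.3
    fwhm_tf_freq_hz: float = 17.7
    representation: str = "tf_fourier"
    stop_accuracy: float = 90.0
    svm_c: float = 1.0
    seed: int = 0
    schema_version: int = SCHEMA_VERSION
    extra: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            blob = json.load(fh)
        blob["snr_freqs"] = tuple(blob.get("snr_freqs", SNR_FREQS))
        return cls(**blob)


def write_trial_log(log: pd.DataFrame, path) -> None:
    """Write a trial log to CSV (snr_values as ';'-joined repr floats)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(LOG_COLUMNS + ["schema_version"])
        for rec in log.itertuples(index=False):
            w.writerow([
                rec.participant_id, rec.session, rec.block, rec.trial_index,
                rec.condition, rec.word, repr(float(rec.contrast)), rec.snr_seed,
                ";".join(repr(float(v)) for v in rec.snr_values),
                int(rec.correct), SCHEMA_VERSION,
            ])


def read_trial_log(path, n_frames: int = N_FRAMES) -> pd.DataFrame:
    """Read a trial log written by :func:`write_trial_log`.

    Malformed rows raise with their line number; a wrong header raises
    listing the missing columns.
    """
    rows = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise ValueError(f"{path}: empty file")
        missing = [c for c in LOG_COLUMNS if c not in header]
        if missing:
            raise ValueError(f"{path}: header missing columns {missing}")
        idx = {c: header.index(c) for c in LOG_COLUMNS}
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                snr = np.asarray([float(v) for v in row[idx["snr_values"]].split(";")])
                if snr.size != n_frames:
                    raise ValueError(f"expected {n_frames} SNR values, got {snr.size}")
                rows.append({
                    "participant_id": _maybe_int(row[idx["participant_id"]]),
                    "session": int(row[idx["session"]]),
                    "block": int(row[idx["block"]]),
                    "trial_index": int(row[idx["trial_index"]]),
                    "condition": int(row[idx["condition"]]),
                    "word": row[idx["word"]],
                    "contrast": float(row[idx["contrast"]]),
                    "snr_seed": int(row[idx["snr_seed"]]),
                    "snr_values": snr,
                    "correct": bool(int(row[idx["correct"]])),
                })
            except ValueError as err:
                raise ValueError(f"{path}: malformed row at line {lineno}: {err}") from None
    return pd.DataFrame(rows, columns=LOG_COLUMNS)


def _maybe_int(s: str):
    try:
        return int(s)
    except ValueError:
        return s
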