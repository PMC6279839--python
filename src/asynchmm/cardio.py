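"""State-matched cardiovascular episode statistics.

Windows decoded to each risk state are matched with the heart-rate and
oxygen-saturation samples recorded over the same windows, and episode
burdens are summarised descriptively per state: the percentage of windows
with at least one episode (%episode) and the mean (SD) percentage of
within-window time spent in episode (tepisode). Episodes follow the usual
clinical thresholds: bradycardia HR < 60 bpm, tachycardia HR > 100 bpm,
hypoxemia SpO2 < 90 %.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["EpisodeThresholds", "detect_episodes", "state_matched_stats"]

EPISODE_TYPES = ("bradycardia", "tachycardia", "hypoxemia")


@dataclass(frozen=True)
class EpisodeThresholds:
    bradycardia: float = 60.0    # HR below this, bpm
    tachycardia: float = 100.0   # HR above this, bpm
    hypoxemia: float = 90.0      # SpO2 below this, %

    def __post_init__(self):
        if self.bradycardia >= self.tachycardia:
            raise ValueError("bradycardia bound must be below tachycardia bound")


def detect_episodes(cardio: pd.DataFrame,
                    thresholds: EpisodeThresholds = EpisodeThresholds(),
                    n_windows: int | None = None) -> pd.DataFrame:
    """Per-window episode flags and within-window time fractions.

    ``cardio`` holds within-window samples with columns ``window`` (int),
    ``hr`` and ``spo2``; samples are treated as equally spaced, so the time
    fraction in episode is the fraction of samples beyond the threshold.
    Windows without samples yield NaN rows (missing, never zero).
    """
    if n_windows is None:
        n_windows = int(cardio["window"].max()) + 1 if len(cardio) else 0
    ind = pd.DataFrame({
        "window": cardio["window"],
        "bradycardia": (cardio["hr"] < thresholds.bradycardia).astype(float),
        "tachycardia": (cardio["hr"] > thresholds.tachycardia).astype(float),
        "hypoxemia": (cardio["spo2"] < thresholds.hypoxemia).astype(float),
    })
    frac = ind.groupby("window").mean()
    out = pd.DataFrame(index=pd.RangeIndex(n_windows, name="window"))
    for ep in EPISODE_TYPES:
        out[f"frac_{ep}"] = frac[ep] if ep in frac else np.nan
        fr = out[f"frac_{ep}"]
        # 1.0/0.0 flag, NaN where the window has no samples
        out[f"any_{ep}"] = (fr > 0).astype(float).where(fr.notna())
    return out.reset_index()


def state_matched_stats(viterbi_path: np.ndarray, episodes: pd.DataFrame,
                        K: int | None = None) -> pd.DataFrame:
    """Episode burden per decoded state.

    For each state and episode type: ``pct_windows`` = 100 x (windows in
    the state with >= 1 episode) / (windows in the state), plus the mean
    and SD of the within-window time percentage. Windows with missing
    cardio samples are excluded; a state with no (non-missing) windows has
    NaN statistics rather than zeros.
    """
    path = np.asarray(viterbi_path)
    if len(episodes) != path.size:
        raise ValueError("viterbi path and episode table lengths disagree")
    if K is None:
        K = int(path.max()) + 1
    rows = []
    for state in range(K):
        mask = path == state
        for ep in EPISODE_TYPES:
            frac = episodes.loc[mask, f"frac_{ep}"].to_numpy(dtype=float)
            frac = frac[~np.isnan(frac)]
            if frac.size == 0:
                rows.append({"state": state, "episode": ep,
                             "n_windows": 0, "pct_windows": np.nan,
                             "t_mean_pct": np.nan, "t_sd_pct": np.nan})
                continue
            rows.append({
                "state": state,
                "episode": ep,
                "n_windows": int(frac.size),
                "pct_windows": 100.0 * float(np.mean(frac > 0)),
                "t_mean_pct": 100.0 * float(frac.mean()),
                "t_sd_pct": 100.0 * float(frac.std(ddof=0)),
            })
    return pd.DataFrame(rows)
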