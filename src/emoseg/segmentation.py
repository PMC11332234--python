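"""Per-participant segmentation grain and agreement metrics.

Mean Length of Unit (MLU) is stimulus duration divided by the number of
pauses: large values mean coarse segmentation. Segmentation Agreement (SA)
compares a participant's 1-s binned pause series with the group's pause
density via a point-biserial correlation, scaled by the best correlation an
ideal observer with the same number of pauses could reach, so SA lies in
[0, 1] regardless of how many pauses the participant made.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import Dataset

logger = logging.getLogger(__name__)


def compute_mlu(n_pauses: int, duration: float) -> float:
    """Mean Length of Unit: ``duration / n_pauses`` seconds; NaN for 0 pauses."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    if n_pauses <= 0:
        return float("nan")
    return duration / n_pauses


def bin_pauses(pauses, duration: float, bin_width: float = 1.0) -> np.ndarray:
    """Binary pause indicator over half-open 1-s bins [k*w, (k+1)*w).

    The final bin is closed at ``duration`` so a pause exactly at the end of
    the clip still counts. Multiple pauses in a bin yield a single 1.
    """
    n_bins = int(np.ceil(duration / bin_width))
    out = np.zeros(n_bins, dtype=int)
    for t in np.atleast_1d(np.asarray(pauses, dtype=float)):
        if t < 0 or t > duration:
            raise ValueError(f"pause at {t} s outside [0, {duration}]")
        k = min(int(t // bin_width), n_bins - 1)
        out[k] = 1
    return out


def ideal_binary_vector(group_density: np.ndarray, k: int) -> np.ndarray:
    """Binary vector with k ones in the k highest-density bins (earlier bins on ties)."""
    d = np.asarray(group_density, dtype=float)
    # stable sort on -density keeps earlier bins first among ties
    order = np.argsort(-d, kind="stable")
    ideal = np.zeros(d.shape, dtype=int)
    ideal[order[:k]] = 1
    return ideal


def compute_sa(
    individual: np.ndarray, group_density: np.ndarray, return_raw: bool = False
) -> float | tuple[float, float]:
    """Scaled point-biserial agreement between one series and the group density.

    ``r_obs`` is the Pearson correlation of the binary individual series with
    the group density series; ``r_max`` the correlation achieved by placing
    the same number of ones in the highest-density bins. SA = r_obs / r_max
    clamped to [0, 1]. A flat group density (or a participant with 0 or all
    bins marked) gives NaN.
    """
    x = np.asarray(individual, dtype=float)
    d = np.asarray(group_density, dtype=float)
    if x.shape != d.shape:
        raise ValueError("individual and group_density must have equal length")
    k = int(x.sum())
    if np.ptp(d) == 0 or k == 0 or k == len(x):
        logger.info("compute_sa: degenerate input (flat density or trivial vector) -> NaN")
        return (float("nan"), float("nan")) if return_raw else float("nan")
    r_obs = np.corrcoef(x, d)[0, 1]
    r_max = np.corrcoef(ideal_binary_vector(d, k), d)[0, 1]
    sa = float(np.clip(r_obs / r_max, 0.0, 1.0))
    return (sa, float(r_obs)) if return_raw else sa


def segmentation_metrics_table(
    ds: Dataset, block: str = "affective", bin_width: float = 1.0, self_included: bool = True
) -> pd.DataFrame:
    """Long table of per-participant, per-stimulus MLU and SA.

    Group density for SA sums the binned series over participants; by default
    the scored participant is included in the norm (``self_included=False``
    gives the leave-one-out variant). Columns: participant_id, stimulus_id,
    n_pauses, mlu, sa.
    """
    rows = []
    for stim in ds.stimuli_in_block(block):
        by_p = ds.pauses_by_participant(stim.stimulus_id)
        binned = {p: bin_pauses(t, stim.duration, bin_width) for p, t in by_p.items()}
        if not binned:
            continue
        density = np.sum(list(binned.values()), axis=0)
        for p, vec in binned.items():
            d = density - vec if not self_included else density
            rows.append(
                {
                    "participant_id": p,
                    "stimulus_id": stim.stimulus_id,
                    "n_pauses": int(len(by_p[p])),
                    "mlu": compute_mlu(len(by_p[p]), stim.duration),
                    "sa": compute_sa(vec, d),
                }
            )
    return pd.DataFrame(rows, columns=["participant_id", "stimulus_id", "n_pauses", "mlu", "sa"])


def participant_means(long_table: pd.DataFrame, metrics: list[str]) -> pd.DataFrame:
    """Average per-stimulus metric values across stimuli, per participant."""
    return long_table.groupby("participant_id")[metrics].mean().reset_index()
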