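"""Synthetic GCaMP-like calcium trajectories with recorded ground truth.

Each cell's ratio-normalized trajectory is a flat baseline plus, for
responding cells, a first major post-stimulus peak (Gaussian rise followed
by exponential decay, so the full width at half maximum has the closed form
sigma_rise * sqrt(8 ln 2)/2 + tau_decay * ln 2) and a small number of later
oscillatory bumps, with additive white noise.  All shape parameters are
deterministic functions of the cell's latent responsiveness vector, so the
trajectory generator and the downstream feature extractor can be compared
against exact truth values.

The parametric form is a modeling convenience: only the extracted features
matter downstream, and real trajectories are far more diverse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CalciumSimParams",
    "CalciumTrajectorySet",
    "calcium_truth_features",
    "generate_calcium_trajectories",
]

_HALF_GAUSS = float(np.sqrt(2.0 * np.log(2.0)))  # half-width of a Gaussian at half max, in sigmas
_LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class CalciumSimParams:
    """Timebase and shape constants of the trajectory model.

    The defaults emulate the acquisition protocol: samples every 2 s for
    16 min with the ATP stimulus at 3 min, trajectories expressed as a
    GCaMP/mCherry ratio with baseline ~1.
    """

    sample_interval: float = 2.0  # s
    duration: float = 960.0  # s
    stim_time: float = 180.0  # s
    baseline: float = 1.0  # ratio units
    noise_sd: float = 0.05
    rise_sigma: float = 4.0  # s, Gaussian rise of the first peak
    response_threshold: float = -1.0  # cells with ca_latent_0 below this do not respond
    peak_delay: float = 8.0  # s from stimulus to earliest peak
    osc_period: float = 60.0  # s between oscillatory bumps
    osc_sigma: float = 8.0  # s, width of oscillatory bumps
    osc_rel_amp: float = 0.35  # bump amplitude relative to the first peak

    def __post_init__(self):
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")
        if not (0 <= self.stim_time < self.duration):
            raise ValueError("stim_time must fall inside the record")

    @property
    def null_sentinel(self) -> float:
        """Value used for peak-derived features when no peak exists."""
        return self.duration + 1.0


def _softplus(x):
    return np.logaddexp(0.0, x)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def calcium_truth_features(states: pd.DataFrame, params: CalciumSimParams | None = None) -> pd.DataFrame:
    """Ground-truth calcium features as deterministic functions of the
    latent responsiveness vector (ca_latent_0..2).

    ca_latent_0 gates responsiveness and sets the first-peak amplitude,
    ca_latent_1 sets the peak width (FWHM 25-35 s), and ca_latent_2 sets
    the number of later oscillatory bumps (0-2).  Non-responding cells get
    the documented null sentinel (duration + 1 s) for time-valued features
    and 0 for counts/AUCs, flagged in ``ca_no_peak``.
    """
    p = params or CalciumSimParams()
    l0 = states["ca_latent_0"].to_numpy(dtype=float)
    l1 = states["ca_latent_1"].to_numpy(dtype=float)
    l2 = states["ca_latent_2"].to_numpy(dtype=float)

    responder = l0 > p.response_threshold
    amplitude = _softplus(1.0 + l0)
    fwhm = 25.0 + 10.0 * _sigmoid(l1)
    # rise width varies between cells so decay time and FWHM carry
    # independent information (they are not affinely linked)
    rise_sigma = p.rise_sigma * (0.5 + 1.0 * _sigmoid(l2))
    tau_d = (fwhm - rise_sigma * _HALF_GAUSS) / _LN2
    peak_time = p.stim_time + p.peak_delay + 4.0 * _sigmoid(-l0)
    n_osc = np.floor(2.5 * _sigmoid(l2)).astype(int)
    n_osc = np.clip(n_osc, 0, 2)
    # keep oscillatory bumps inside the record
    max_osc = np.floor((p.duration - 2 * p.osc_sigma - peak_time) / p.osc_period).astype(int)
    n_osc = np.minimum(n_osc, np.maximum(max_osc, 0))

    osc_amp = p.osc_rel_amp * amplitude
    peak_auc = amplitude * (rise_sigma * np.sqrt(np.pi / 2.0) + tau_d)
    osc_auc = n_osc * osc_amp * p.osc_sigma * np.sqrt(2.0 * np.pi)

    sent = p.null_sentinel
    out = pd.DataFrame(index=states.index)
    out["ca_n_peaks_low"] = np.where(responder, 1 + n_osc, 0)
    out["ca_n_peaks_high"] = np.where(responder, n_osc, 0)
    out["ca_decay_time"] = np.where(responder, tau_d, sent)
    out["ca_fwhm"] = np.where(responder, fwhm, sent)
    out["ca_auc_low"] = np.where(responder, peak_auc + osc_auc, 0.0)
    out["ca_auc_high"] = np.where(responder, osc_auc, 0.0)
    out["ca_max_value"] = np.where(responder, p.baseline + amplitude, p.baseline)
    out["ca_time_of_max"] = np.where(responder, peak_time, sent)
    out["ca_no_peak"] = ~responder
    # internal shape parameters, used by the renderer
    out["_amplitude"] = np.where(responder, amplitude, 0.0)
    out["_tau_d"] = tau_d
    out["_rise_sigma"] = rise_sigma
    out["_peak_time"] = peak_time
    out["_n_osc"] = np.where(responder, n_osc, 0)
    return out


@dataclass
class CalciumTrajectorySet:
    """Trajectories on a common timebase plus their generating truth."""

    t: np.ndarray  # (n_t,)
    values: np.ndarray  # (n_cells, n_t) ratio units
    truth: pd.DataFrame  # per-cell truth features (public ca_* columns)
    params: CalciumSimParams
    cell_ids: np.ndarray

    def to_long_dataframe(self) -> pd.DataFrame:
        n, m = self.values.shape
        return pd.DataFrame(
            {
                "cell_id": np.repeat(self.cell_ids, m),
                "t": np.tile(self.t, n),
                "value": self.values.ravel(),
            }
        )


def generate_calcium_trajectories(
    states: pd.DataFrame,
    params: CalciumSimParams | None = None,
    seed: int = 0,
) -> CalciumTrajectorySet:
    """Render noisy trajectories from the per-cell truth parameters.

    Same states + params + seed always produce identical trajectories.
    """
    p = params or CalciumSimParams()
    truth = calcium_truth_features(states, p)
    t = np.arange(0.0, p.duration + 0.5 * p.sample_interval, p.sample_interval)
    n_cells = len(states)

    amp = truth["_amplitude"].to_numpy()
    tau_d = truth["_tau_d"].to_numpy()
    rise_sigma = truth["_rise_sigma"].to_numpy()
    tp = truth["_peak_time"].to_numpy()
    n_osc = truth["_n_osc"].to_numpy(dtype=int)

    dt_mat = t[None, :] - tp[:, None]
    rise = np.exp(-0.5 * (dt_mat / rise_sigma[:, None]) ** 2)
    decay = np.exp(-np.clip(dt_mat, 0.0, None) / tau_d[:, None])
    peak = np.where(dt_mat < 0, rise, decay)
    values = p.baseline + amp[:, None] * peak
    max_osc = int(n_osc.max()) if n_cells else 0
    for k in range(1, max_osc + 1):
        has = n_osc >= k
        center = tp + k * p.osc_period
        bump = np.exp(-0.5 * ((t[None, :] - center[:, None]) / p.osc_sigma) ** 2)
        values += np.where(has[:, None], p.osc_rel_amp * amp[:, None] * bump, 0.0)

    rng = np.random.default_rng(seed)
    if p.noise_sd > 0:
        values = values + rng.normal(0.0, p.noise_sd, values.shape)

    public = truth[[c for c in truth.columns if not c.startswith("_")]].copy()
    return CalciumTrajectorySet(
        t=t,
        values=values,
        truth=public,
        params=p,
        cell_ids=states["cell_id"].to_numpy(),
    )
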