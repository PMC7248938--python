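"""Shared scaled-down study settings and end-to-end helpers for the tests.

The synthetic study used throughout: a 12-locus upper-hemisphere array,
a 200-vertex labeled mesh, 60 trials over ~6 minutes at 200 Hz, an 8-band
4-40 Hz filterbank, and a 20 Hz burst planted over the Lmot analogue with a
0.4 s cue-to-response delay.
"""

from __future__ import annotations

import numpy as np

import msamap as m

FS = 200.0
N_BANDS = 8
F_MIN, F_MAX = 4.0, 40.0
TARGET_BAND = 20.0
DELAY = 0.4


def make_study(seed: int, *, n_loci: int = 12, n_vertices: int = 200,
               n_trials: int = 60, duration: float = 365.0,
               gain: float = 2.0, jitter: float = 0.1,
               delay: float = DELAY, target_region: str = "Lmot"):
    """Geometry + simulated session with planted activity over a region."""
    array = m.make_sensor_array(n_loci, seed=seed)
    mesh = m.make_cortical_mesh(n_vertices, array, seed=seed + 1000)
    targets = m.pick_target_loci(array, mesh, target_region)
    cfg = m.SimConfig(fs=FS, duration=duration, n_trials=n_trials,
                      target_loci=targets, target_band=TARGET_BAND,
                      response_delay=delay, jitter_sd=jitter,
                      modulation_gain=gain, seed=seed)
    session, truth = m.simulate_session(cfg, array)
    return array, mesh, targets, session, truth


def analyze(session, onsets, *, n_folds: int = 4, lam: float = 1.0,
            shifts=None):
    """Features -> event train -> per-locus cross-validated MPC map."""
    bank = m.morlet_filterbank(F_MIN, F_MAX, N_BANDS)
    feats = m.compute_features(session, bank)
    ev = m.frame_event_train(onsets, feats)
    if shifts is None:
        shifts = m.default_shift_grid(feats.step)
    return feats, ev, m.msa_map(feats, ev, shifts, n_folds=n_folds, lam=lam)


def lmot_selectivity(mpc, array, mesh, target_region: str = "Lmot",
                     q: float = 0.95):
    """Project an MPC map and summarize target-region selectivity."""
    values = np.where(np.isfinite(mpc.values), mpc.values, 0.0)
    cmap = m.project_map(values, mpc.shifts, array, mesh)
    rts = m.detect_significant(m.region_timecourse(cmap), q)
    return m.selectivity_summary(rts, target_region), rts
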