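"""Independent oracle helpers shared by the test suite.

Everything here is deliberately written with explicit loops / basic
numpy, independent of the library code paths it is used to check.
"""

import numpy as np

from pflow.experiment_analysis import TrialRecord, measurement_stimuli


def build_session_trials(rng, n_blocks=5, sigma=5.0):
    """A structurally valid 5x10 measurement session with Gaussian errors."""
    stims = measurement_stimuli("pflow")
    trials = []
    idx = 0
    for b in range(1, n_blocks + 1):
        for si in rng.permutation(len(stims)):
            st = stims[si]
            idx += 1
            trials.append(TrialRecord(
                participant_id="p0", block=b, trial_index=idx, stimulus=st,
                actual_rating=st.expected_rating + rng.normal(0, sigma),
                rt=float(rng.uniform(2, 20))))
    return trials


def bilinear_warp_wrap(frame, velocity):
    """Forward warp by v with periodic boundaries (independent of scipy)."""
    h, w = frame.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    sx = (xx - velocity[..., 0]) % w
    sy = (yy - velocity[..., 1]) % h
    x0 = np.floor(sx).astype(int)
    y0 = np.floor(sy).astype(int)
    fx, fy = sx - x0, sy - y0
    x1, y1 = (x0 + 1) % w, (y0 + 1) % h
    return (frame[y0, x0] * (1 - fx) * (1 - fy)
            + frame[y0, x1] * fx * (1 - fy)
            + frame[y1, x0] * (1 - fx) * fy
            + frame[y1, x1] * fx * fy)


def bruteforce_splitplot_f(y, gidx):
    """Split-plot F statistics from explicit group means and loops."""
    y = np.asarray(y, dtype=float)
    N, s = y.shape
    labels = sorted(set(gidx.tolist()))
    a = len(labels)
    grand = y.mean()

    subj_mean = [y[i].mean() for i in range(N)]
    group_rows = {g: [i for i in range(N) if gidx[i] == g] for g in labels}
    group_mean = {g: np.mean([subj_mean[i] for i in group_rows[g]])
                  for g in labels}
    stim_mean = [y[:, j].mean() for j in range(s)]

    ss_total = sum((y[i, j] - grand) ** 2
                   for i in range(N) for j in range(s))
    ss_bs = s * sum((m - grand) ** 2 for m in subj_mean)
    ss_a = s * sum(len(group_rows[g]) * (group_mean[g] - grand) ** 2
                   for g in labels)
    ss_eb = ss_bs - ss_a
    ss_s = N * sum((m - grand) ** 2 for m in stim_mean)
    ss_as = 0.0
    for g in labels:
        rows = group_rows[g]
        for j in range(s):
            cell = np.mean([y[i, j] for i in rows])
            ss_as += len(rows) * (cell - group_mean[g]
                                  - stim_mean[j] + grand) ** 2
    ss_ew = ss_total - ss_bs - ss_s - ss_as

    df_a, df_eb = a - 1, N - a
    df_s, df_as, df_ew = s - 1, (a - 1) * (s - 1), (N - a) * (s - 1)
    f_a = (ss_a / df_a) / (ss_eb / df_eb)
    f_s = (ss_s / df_s) / (ss_ew / df_ew)
    f_as = (ss_as / df_as) / (ss_ew / df_ew)
    return np.array([f_a, f_s, f_as])
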