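"""Shared builders for hand-made feature matrices used across test modules."""

import numpy as np
import pandas as pd

_CLASS_GEOMETRY = {
    # label: (meanRoll, meanAbsDiffRoll, avgDiffFftPeakPower) class means
    "vigilance": (24.0, 2.0, 300.0),
    "resting": (-24.0, 1.5, 300.0),
    "foraging": (3.0, 25.0, 600.0),
    "running": (-1.0, 70.0, 2200.0),
}


def balanced_gaussian_fm(n_per_class=25, seed=0):
    """Separable three-feature matrix with equal class counts."""
    rng = np.random.default_rng(seed)
    rows = []
    for label, (mu_p, mu_i, mu_f) in _CLASS_GEOMETRY.items():
        for j in range(n_per_class):
            rows.append({
                "meanRoll": rng.normal(mu_p, 2.0),
                "meanAbsDiffRoll": rng.normal(mu_i, 2.0),
                "avgDiffFftPeakPower": rng.normal(mu_f, 80.0),
                "label": label,
                "session_id": f"sess{j % 4:02d}",
                "individual_id": f"ind{j % 4:02d}",
                "start_time": float(j),
            })
    return pd.DataFrame(rows)


def multi_session_gaussian_fm(n_individuals=3, sessions_each=2,
                              n_per_class=15, seed=1):
    """Separable matrix with several sessions per individual, every
    session containing all four behaviours."""
    rng = np.random.default_rng(seed)
    rows = []
    session_no = 0
    for ind in range(n_individuals):
        for _ in range(sessions_each):
            session_no += 1
            for label, (mu_p, mu_i, mu_f) in _CLASS_GEOMETRY.items():
                for j in range(n_per_class):
                    rows.append({
                        "meanRoll": rng.normal(mu_p, 2.0),
                        "meanAbsDiffRoll": rng.normal(mu_i, 2.0),
                        "avgDiffFftPeakPower": rng.normal(mu_f, 80.0),
                        "label": label,
                        "session_id": f"sess{session_no:02d}",
                        "individual_id": f"ind{ind + 1:02d}",
                        "start_time": float(j),
                    })
    return pd.DataFrame(rows)
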