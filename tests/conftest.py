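import numpy as np
import pandas as pd
import pytest

import plasmasig as ps


@pytest.fixture(scope="session")
def study():
    """One default-size synthetic study shared across read-only tests."""
    return ps.simulate_study(ps.SimSpec(seed=7))


@pytest.fixture(scope="session")
def preprocessed(study):
    qm, ct, truth = study
    groups = ct.pcr.loc[qm.sample_ids].to_numpy()
    norm, stab, nm, imp = ps.preprocess_pipeline(qm, groups)
    return norm, stab, nm, imp


def brute_force_auc(x, y):
    """Pair-counting oracle: P(positive > negative) + half ties."""
    pos = x[y == 1]
    neg = x[y == 0]
    wins = ties = 0
    for a in pos:
        for b in neg:
            wins += a > b
            ties += a == b
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def brute_force_logrank_z(time, event, g1):
    """Risk-set enumeration oracle for the standardized log-rank statistic."""
    time, event, g1 = map(np.asarray, (time, event, g1))
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(time[event == 1])):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & g1).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e / np.sqrt(var) if var > 0 else 0.0


def make_clinical(subtype_counts, pcr_counts, seed=0):
    """Clinical table with given per-subtype sizes and pCR counts; survival
    columns filled with benign placeholders."""
    rng = np.random.default_rng(seed)
    flags = {"HR+/HER2-": (1, 0), "HR+/HER2+": (1, 1),
             "HER2+": (0, 1), "TN": (0, 0)}
    rows = []
    i = 0
    for subtype, n in subtype_counts.items():
        k = pcr_counts[subtype]
        hr, her2 = flags[subtype]
        for j in range(n):
            t = float(rng.uniform(10, 60))
            rows.append({
                "sample_id": f"S{i:03d}", "pcr": int(j < k),
                "hr_status": hr, "her2_status": her2,
                "age_years": float(rng.uniform(30, 65)),
                "tumor_size_gt5cm": int(rng.random() < 0.3),
                "node_positive": int(rng.random() < 0.7),
                "grade3": int(rng.random() < 0.3),
                "dfs_months": t, "dfs_event": 0,
                "os_months": t, "os_event": 0,
                "dmfs_months": t, "dmfs_event": 0,
            })
            i += 1
    return ps.ClinicalTable(pd.DataFrame(rows))
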