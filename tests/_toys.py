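"""Hand-built toy objects shared across test modules."""

import pandas as pd

from rtpred.annotate import CandidateSet, QueryIon


def make_set(query_id, truth_err, decoy_errs, true_id="truth"):
    """Candidate set with prescribed relative RT errors (truth first)."""
    errs = ([] if truth_err is None else [(true_id, truth_err)]) + [
        (f"d{i}", e) for i, e in enumerate(decoy_errs)
    ]
    df = pd.DataFrame(
        {
            "mol_id": [m for m, _ in errs],
            "theo_mz": 100.0,
            "ppm_error": 0.0,
            "rt_projected_s": 100.0,
            "rel_rt_error_pct": [e for _, e in errs],
        }
    )
    q = QueryIon(
        query_id=query_id,
        mz=101.007276,
        adduct="M+H",
        rt_exp=100.0,
        true_mol_id=None if truth_err is None else true_id,
    )
    return CandidateSet(query=q, candidates=df)


def rank_statistic(correct, incorrect):
    """Tie-corrected probability that a correct identity out-scores an incorrect one."""
    wins = sum((c < i) + 0.5 * (c == i) for c in correct for i in incorrect)
    return wins / (len(correct) * len(incorrect))
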