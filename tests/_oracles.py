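"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's vectorised code paths: plain Python
loops and set algebra only.
"""

import math


def brute_collapse(psms):
    """Group (peptide, is_decoy) -> best score, by explicit iteration."""
    best = {}
    for _, row in psms.iterrows():
        key = (row["peptide"], bool(row["is_decoy"]))
        if key not in best or row["score"] > best[key]:
            best[key] = row["score"]
    return best


def brute_fdr(targets, decoys, cutoff):
    n_t = sum(1 for s in targets if s >= cutoff)
    n_d = sum(1 for s in decoys if s >= cutoff)
    return 0.0 if n_t == 0 else n_d / n_t


def brute_threshold(targets, decoys, alpha):
    """Exhaustively evaluate every observed target score as a cutoff and
    return (smallest feasible cutoff, accepted target scores)."""
    feasible = [c for c in sorted(set(targets)) if brute_fdr(targets, decoys, c) <= alpha]
    if not feasible:
        return math.inf, []
    cutoff = feasible[0]
    return cutoff, [s for s in targets if s >= cutoff]


def brute_rescue_sets(band, high_strict, high_relaxed):
    """Set-algebra oracle for the rescue report counts."""
    recovered_strict = {p for p in band if p in high_strict}
    recovered_extra = {p for p in band if p in high_relaxed and p not in high_strict}
    return len(recovered_strict), len(recovered_extra)
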