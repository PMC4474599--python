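"""Independent brute-force re-derivations used as oracles in tests.

These deliberately re-implement the documented rules from their plain-
English statements with naive loops, sharing no code with the package
internals they check.
"""

from __future__ import annotations

P1 = {"D": 1.0, "E": 0.8, "S": 0.6, "T": 0.6}
P2 = {"S": 1.0, "T": 0.9, "D": 0.8, "E": 0.8}
PLAST = dict(P2)


def brute_force_degron_windows(seq: str, gless_penalty: float = 1.0):
    """Every degron-class substring of ``seq`` with its best score.

    Enumerates all substrings, tests each against the window grammar
    (p1, p2, glycine, 1-4 spacer, p_last — or p1, p2, 1-4 spacer,
    p_last for glycine-less windows) and scores it: class weights plus
    0.05 per D/E/S/T spacer residue capped at 0.2, minus the penalty
    for glycine-less windows.  Returns {(start_1based, end_1based):
    (score, has_glycine)} keeping the best interpretation per span.
    """
    out: dict[tuple[int, int], tuple[float, bool]] = {}
    n = len(seq)
    for a in range(n):
        for b in range(a + 4, min(n, a + 8) + 1):  # substring seq[a:b]
            sub = seq[a:b]
            candidates = []
            # glycine form: length 3 + spacer + 1, spacer 1..4
            if 5 <= len(sub) <= 8:
                spacer = sub[3:-1]
                if (
                    sub[0] in P1
                    and sub[1] in P2
                    and sub[2] == "G"
                    and sub[-1] in PLAST
                    and 1 <= len(spacer) <= 4
                ):
                    bonus = min(0.05 * sum(c in "DEST" for c in spacer), 0.2)
                    candidates.append(
                        (P1[sub[0]] + P2[sub[1]] + PLAST[sub[-1]] + bonus, True)
                    )
            # glycine-less form: length 2 + spacer + 1, spacer 1..4
            if 4 <= len(sub) <= 7:
                spacer = sub[2:-1]
                if (
                    sub[0] in P1
                    and sub[1] in P2
                    and sub[-1] in PLAST
                    and 1 <= len(spacer) <= 4
                ):
                    bonus = min(0.05 * sum(c in "DEST" for c in spacer), 0.2)
                    candidates.append(
                        (
                            P1[sub[0]] + P2[sub[1]] + PLAST[sub[-1]] + bonus - gless_penalty,
                            False,
                        )
                    )
            if candidates:
                best = max(candidates)
                key = (a + 1, b)
                if key not in out or best[0] > out[key][0]:
                    out[key] = best
    return {k: v for k, v in out.items() if v[0] > 0}


def brute_force_calls(
    proteins, counts, baits, min_bait_runs=2, threshold=1, control_threshold=1
):
    """Candidate set re-derived from the rule's English statement.

    counts: dict protein -> dict run_id -> count; baits: run_id -> bait
    name.  A protein is a candidate iff identified (count >= threshold)
    in at least ``min_bait_runs`` non-control runs and identified
    (count >= control_threshold) in zero control runs.
    """
    candidates = set()
    for p in proteins:
        n_bait = 0
        n_ctrl = 0
        for run_id, bait in baits.items():
            if bait == "control":
                n_ctrl += counts[p].get(run_id, 0) >= control_threshold
            else:
                n_bait += counts[p].get(run_id, 0) >= threshold
        if n_bait >= min_bait_runs and n_ctrl == 0:
            candidates.add(p)
    return candidates
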