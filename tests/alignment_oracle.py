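"""Exhaustive-enumeration oracle for global alignment, shared by tests."""

from srnase.protein_features import AlignmentScoring


def brute_force_alignments(a: str, b: str, scoring=AlignmentScoring()):
    """Enumerate every global alignment; return (best score, identities at best)."""
    best = {"score": None, "identities": set()}

    def walk(i, j, cols, matches, score):
        if i == len(a) and j == len(b):
            if best["score"] is None or score > best["score"]:
                best["score"] = score
                best["identities"] = {round(100.0 * matches / cols, 2)}
            elif score == best["score"]:
                best["identities"].add(round(100.0 * matches / cols, 2))
            return
        if i < len(a) and j < len(b):
            walk(i + 1, j + 1, cols + 1, matches + (a[i] == b[j]),
                 score + scoring.score(a[i], b[j]))
        if i < len(a):
            walk(i + 1, j, cols + 1, matches, score + scoring.gap)
        if j < len(b):
            walk(i, j + 1, cols + 1, matches, score + scoring.gap)

    walk(0, 0, 0, 0, 0.0)
    return best["score"], best["identities"]
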