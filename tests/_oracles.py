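"""Self-contained reference oracles used by several test modules.

Deliberately independent of rflpkit internals: own IUPAC tables, own
complement map, every-offset scanning.
"""

_ORACLE_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT", "S": "CG",
    "W": "AT", "K": "GT", "M": "AC", "B": "CGT", "D": "AGT", "H": "ACT",
    "V": "ACG", "N": "ACGT",
}
_ORACLE_COMP = dict(zip("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN"))


def _oracle_match_at(seq, pat, i):
    return all(
        set(_ORACLE_SETS[seq[i + j]]) <= set(_ORACLE_SETS[p]) for j, p in enumerate(pat)
    )


def naive_sites(seq: str, enzyme):
    """Every-offset both-strand scan; returns {(start, orientation, cut)}.

    ``enzyme`` needs ``pattern`` and ``cut5`` attributes.  For a reverse
    site the pattern is read 5'->3' on the bottom strand; its cut maps
    to top coordinate ``i + m - cut5``.
    """
    L, m = len(seq), len(enzyme.pattern)
    rc_pat = "".join(_ORACLE_COMP[c] for c in reversed(enzyme.pattern))
    out = set()
    for i in range(L - m + 1):
        if _oracle_match_at(seq, enzyme.pattern, i):
            cut = i + enzyme.cut5
            if 0 <= cut <= L:
                out.add((i, "forward", cut))
    if enzyme.pattern != rc_pat:  # non-palindromic: scan the other strand
        for i in range(L - m + 1):
            if _oracle_match_at(seq, rc_pat, i):
                cut = i + m - enzyme.cut5
                if 0 <= cut <= L:
                    out.add((i, "reverse", cut))
    return out
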