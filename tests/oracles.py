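"""Independent brute-force oracles used to validate the production code.

These deliberately avoid the production algorithms: the motif oracle
enumerates every start and every combination of element lengths via
itertools.product and verifies the assembled assignment with plain zip
checks; the end-repeat oracle compares every prefix/suffix length directly;
the rotation oracle takes the minimum over all rotations.
"""

import itertools

from permuzyme.motif import CleavageSite, HelixClose, HelixOpen, IUPAC, SingleStrand
from permuzyme.search import revcomp

_WC_GU = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def _char_ok(p, s):
    if s == "N":
        return p == "N"
    return s in IUPAC[p]


def brute_force_matches(descriptor, seq, strands=("+", "-"), allow_gu=True):
    """Set of (strand, start, lengths-tuple, cleavage offset) for all matches."""
    out = set()
    L = len(seq)
    elements = descriptor.elements
    # per-element length options (helix close length mirrors its open)
    options = []
    for el in elements:
        if isinstance(el, HelixOpen):
            options.append(list(range(el.min_len, el.max_len + 1)))
        elif isinstance(el, SingleStrand) and not el.fixed:
            options.append(list(range(el.min_len, el.max_len + 1)))
        else:
            options.append([None])  # length implied

    for strand in strands:
        subject = seq if strand == "+" else revcomp(seq)
        for combo in itertools.product(*options):
            # resolve element lengths
            open_len = {}
            lengths = []
            ok = True
            for el, k in zip(elements, combo):
                if isinstance(el, HelixOpen):
                    open_len[el.label] = k
                    lengths.append(k)
                elif isinstance(el, HelixClose):
                    lengths.append(open_len[el.label])
                elif isinstance(el, CleavageSite):
                    lengths.append(0)
                elif el.fixed:
                    lengths.append(el.min_len)
                else:
                    lengths.append(k)
            total = sum(lengths)
            if total > L:
                continue
            for start in range(L - total + 1):
                pos = start
                spans = []
                for el, k in zip(elements, lengths):
                    spans.append((el, pos, k))
                    pos += k
                ok = True
                cleave = None
                open_span = {}
                for el, p, k in spans:
                    if isinstance(el, HelixOpen):
                        open_span[el.label] = (p, k, el.mismatches)
                    elif isinstance(el, HelixClose):
                        op, ok_len, mm_budget = open_span[el.label]
                        mm = sum(
                            (subject[op + j], subject[p + ok_len - 1 - j]) not in _WC_GU
                            for j in range(ok_len)
                        )
                        if mm > mm_budget:
                            ok = False
                            break
                    elif isinstance(el, CleavageSite):
                        cleave = p - start
                    elif isinstance(el, SingleStrand):
                        if el.fixed:
                            if not all(
                                _char_ok(pc, sc)
                                for pc, sc in zip(el.pattern, subject[p:p + k])
                            ):
                                ok = False
                                break
                        else:
                            if not all(
                                _char_ok(el.pattern, sc) for sc in subject[p:p + k]
                            ):
                                ok = False
                                break
                if ok and cleave is not None:
                    key_lengths = tuple(lengths)
                    if strand == "+":
                        out.add(("+", start, key_lengths, cleave))
                    else:
                        out.add(("-", L - (start + total), key_lengths, cleave))
    return out


def match_key(m):
    """Comparable key for a production MotifMatch."""
    lengths = tuple(sp.length for sp in m.spans)
    return (m.strand, m.start, lengths, m.cleavage_offset)


def brute_force_end_repeat(seq, min_len):
    """Longest k in [min_len, L//2] with exact prefix == suffix, else None."""
    s = seq.upper().replace("T", "U")
    L = len(s)
    best = None
    for k in range(min_len, L // 2 + 1):
        if "N" not in s[:k] and s[:k] == s[L - k:]:
            best = k
    return best


def brute_force_min_rotation(s):
    return min(s[i:] + s[:i] for i in range(len(s)))
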