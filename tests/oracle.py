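"""Independent brute-force reference for elimination and scoring.

Deliberately shares no code with polytg.scoring/polytg.model: patterns are
built by explicit string padding, elimination and the difference score by
plain Python loops over base sets.  Used to cross-check the vectorized
pipeline on simulated samples.
"""

from __future__ import annotations

COL = {"A": 0, "C": 1, "G": 2, "T": 3}


def canonical_label(p1, p2):
    (m1, n1), (m2, n2) = sorted((p1, p2), key=lambda p: (2 * p[0] + p[1], p[0]))
    return f"(TG){m1}T{n1}/(TG){m2}T{n2}"


def _sets(seqs, length, align):
    out = []
    for p in range(length):
        bases = set()
        for sq in seqs:
            q = p if align == "left" else p - (length - len(sq))
            if 0 <= q < len(sq):
                bases.add(sq[q])
        out.append(bases)
    return out


def _signal_absent(profile, pos, base, presence):
    """True only when absence is assertable (informative, in-read)."""
    if pos < 0 or pos >= len(profile) or not profile.informative[pos]:
        return False
    return profile.rel[pos, COL[base]] < presence


def brute_force_rank(tract_f, tract_r, space, presence=0.10):
    """Return {canonical label: (eliminated, d or None)} for every genotype."""
    alleles = [
        (m, n)
        for m in range(space.min_tg, space.max_tg + 1)
        for n in range(space.min_t, space.max_t + 1)
    ]
    prof_f, prof_r = tract_f.profile, tract_r.profile
    n_f, n_r = tract_f.length, tract_r.length
    results = {}
    for i in range(len(alleles)):
        for j in range(i, len(alleles)):
            pair = (alleles[i], alleles[j])
            seqs = ["TG" * m + "T" * n for m, n in pair]
            length = max(len(s) for s in seqs)
            fwd_sets = _sets(seqs, length, "left")
            rev_sets = _sets(seqs, length, "right")

            eliminated = False
            for p, bases in enumerate(fwd_sets):
                if len(bases) == 1 and _signal_absent(
                    prof_f, tract_f.start + p, next(iter(bases)), presence
                ):
                    eliminated = True
                    break
            if not eliminated:
                for p, bases in enumerate(rev_sets):
                    pos = tract_r.end - (length - p)
                    if len(bases) == 1 and _signal_absent(
                        prof_r, pos, next(iter(bases)), presence
                    ):
                        eliminated = True
                        break

            label = canonical_label(*pair)
            if eliminated:
                results[label] = (True, None)
                continue

            num = 0.0
            for p in range(n_f):
                if not tract_f.informative_mask[p]:
                    continue
                et, eg = _expected(fwd_sets, p)
                num += (tract_f.og[p] - eg) ** 2 + (tract_f.ot[p] - et) ** 2
            for p in range(n_r):
                q = length - (n_r - p)
                if not tract_r.informative_mask[p]:
                    continue
                et, eg = _expected(rev_sets, q)
                num += (tract_r.og[p] - eg) ** 2 + (tract_r.ot[p] - et) ** 2
            d = num / (2.0 * (n_f + n_r)) + (100 - 2 * length) / 1e5
            results[label] = (False, d)
    return results


def _expected(sets, p):
    if not 0 <= p < len(sets):
        return 0.0, 0.0
    bases = sets[p]
    if bases == {"T"}:
        return 1.0, 0.0
    if bases == {"G"}:
        return 0.0, 1.0
    return 0.5, 0.5
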