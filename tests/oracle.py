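"""Independent direct-evaluation oracle for the normalization pipeline.

Every formula is evaluated with plain Python loops and dicts, sharing no
code with the package: abundance = count / (length * sample total);
reference profile = per-gene mean over genes non-zero everywhere;
M = log2 relative-abundance ratio, A = half the log2 product,
w = 1/Y_gk + 1/Y_ref; min-max trimming with strict double inequalities;
factor = 2 ** (sum(w*M)/sum(w)) over the kept genes.
"""

import math


def oracle_factors(counts, lengths, m_lower=0.3, m_upper=0.7,
                   a_lower=0.2, a_upper=0.8):
    """counts: {sample: {gene: int}}, lengths: {gene: int}.

    Returns {sample: R} or None when some sample's trimmed set is empty.
    """
    samples = list(counts)
    genes = list(lengths)

    cleaned = {k: {g: (counts[k][g] if counts[k][g] >= 2 else 0)
                   for g in genes} for k in samples}
    totals = {k: sum(cleaned[k].values()) for k in samples}
    Y = {k: {g: cleaned[k][g] / (lengths[g] * totals[k]) for g in genes}
         for k in samples}
    N = {k: sum(Y[k].values()) for k in samples}

    G = [g for g in genes if all(Y[k][g] != 0 for k in samples)]
    if not G:
        return None
    y_ref = {g: sum(Y[k][g] for k in samples) / len(samples) for g in G}
    n_ref = sum(y_ref.values())

    factors = {}
    for k in samples:
        m, a, w = {}, {}, {}
        for g in G:
            rel_k = Y[k][g] / N[k]
            rel_r = y_ref[g] / n_ref
            m[g] = math.log2(rel_k / rel_r)
            a[g] = 0.5 * math.log2(rel_k * rel_r)
            w[g] = 1.0 / Y[k][g] + 1.0 / y_ref[g]
        m_min, m_max = min(m.values()), max(m.values())
        a_min, a_max = min(a.values()), max(a.values())
        kept = []
        for g in G:
            if m_max > m_min:
                qm = (m[g] - m_min) / (m_max - m_min)
                if not (m_lower < qm < m_upper):
                    continue
            if a_max > a_min:
                qa = (a[g] - a_min) / (a_max - a_min)
                if not (a_lower < qa < a_upper):
                    continue
            kept.append(g)
        if not kept:
            return None
        log_tmm = sum(w[g] * m[g] for g in kept) / sum(w[g] for g in kept)
        factors[k] = 2.0 ** log_tmm
    return factors
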