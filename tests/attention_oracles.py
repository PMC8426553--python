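"""Element-wise (scalar-loop) oracles for the attention equations.

Deliberately written with explicit Python loops and scalar arithmetic so
they share no code path with the vectorized implementation they check.
"""

import math

import numpy as np


def loop_single_head(o_all, o_last, w_t, lengths):
    """Element-wise implementation of s = softmax(o_last (o_all W_t)^H),
    o_t = s o_all."""
    b_sz, t_len, z = o_all.shape
    scores = np.zeros((b_sz, t_len))
    contexts = np.zeros((b_sz, z))
    for b in range(b_sz):
        logits = []
        for t in range(lengths[b]):
            acc = 0.0
            for i in range(z):
                proj = sum(o_all[b, t, j] * w_t[j, i] for j in range(z))
                acc += o_last[b, 0, i] * proj
            logits.append(acc)
        mx = max(logits)
        exps = [math.exp(v - mx) for v in logits]
        total = sum(exps)
        for t in range(lengths[b]):
            scores[b, t] = exps[t] / total
        for i in range(z):
            contexts[b, i] = sum(scores[b, t] * o_all[b, t, i] for t in range(lengths[b]))
    return scores, contexts


def loop_multi_head(o_all, o_last, heads, lengths, scale=False):
    """Element-wise K_i/V_i/Q_i projection, masked softmax and context."""
    b_sz, t_len, z = o_all.shape
    n = len(heads)
    d = z // n
    all_scores = np.zeros((n, b_sz, t_len))
    cv = np.zeros((b_sz, z))
    for h, hp in enumerate(heads):
        for b in range(b_sz):
            k = np.zeros((t_len, d))
            v = np.zeros((t_len, d))
            q = np.zeros(d)
            for t in range(t_len):
                for c in range(d):
                    k[t, c] = sum(o_all[b, t, j] * hp["wk"][j, c] for j in range(z)) + hp["bk"][c]
                    v[t, c] = sum(o_all[b, t, j] * hp["wv"][j, c] for j in range(z)) + hp["bv"][c]
            for c in range(d):
                q[c] = sum(o_last[b, 0, j] * hp["wq"][j, c] for j in range(z)) + hp["bq"][c]
            alpha = 1.0 / math.sqrt(d) if scale else 1.0
            logits = [alpha * sum(q[c] * k[t, c] for c in range(d)) for t in range(lengths[b])]
            mx = max(logits)
            exps = [math.exp(x - mx) for x in logits]
            total = sum(exps)
            s = [e / total for e in exps]
            for t in range(lengths[b]):
                all_scores[h, b, t] = s[t]
            for c in range(d):
                cv[b, h * d + c] = sum(s[t] * v[t, c] for t in range(lengths[b]))
    return all_scores, cv


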