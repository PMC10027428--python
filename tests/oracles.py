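"""Independent plain-loop reference implementations of every loss.

Deliberately written with explicit Python loops and math-library calls only,
sharing no code with the package, so agreement with the vectorised
implementations is a genuine cross-check.
"""

import math

IGNORE = -100
FLOOR = 1e-12


def softmax_row(row):
    m = max(row)
    exps = [math.exp(x - m) for x in row]
    z = sum(exps)
    return [e / z for e in exps]


def _masked_positions(labels):
    out = []
    flat_labels = labels.reshape(-1)
    for n in range(flat_labels.shape[0]):
        if flat_labels[n] != IGNORE:
            out.append(n)
    return out


def mlm_loss_loop(logits, labels):
    """Mean cross-entropy over positions with a real label."""
    L = logits.reshape(-1, logits.shape[-1])
    y = labels.reshape(-1)
    total, count = 0.0, 0
    for n in range(L.shape[0]):
        if y[n] == IGNORE:
            continue
        p = softmax_row(list(L[n]))
        total += -math.log(p[int(y[n])] + FLOOR)
        count += 1
    return total / count if count else 0.0


def output_kl_loop(s_logits, t_logits, labels):
    S = s_logits.reshape(-1, s_logits.shape[-1])
    T = t_logits.reshape(-1, t_logits.shape[-1])
    y = labels.reshape(-1)
    total, count = 0.0, 0
    for n in range(S.shape[0]):
        if y[n] == IGNORE:
            continue
        ps, pt = softmax_row(list(S[n])), softmax_row(list(T[n]))
        total += sum(a * (math.log(a + FLOOR) - math.log(b + FLOOR))
                     for a, b in zip(ps, pt))
        count += 1
    return total / count if count else 0.0


def output_ce_loop(s_logits, t_logits, labels):
    S = s_logits.reshape(-1, s_logits.shape[-1])
    T = t_logits.reshape(-1, t_logits.shape[-1])
    y = labels.reshape(-1)
    total, count = 0.0, 0
    for n in range(S.shape[0]):
        if y[n] == IGNORE:
            continue
        ps, pt = softmax_row(list(S[n])), softmax_row(list(T[n]))
        total += -sum(b * math.log(a + FLOOR) for a, b in zip(ps, pt))
        count += 1
    return total / count if count else 0.0


def cosine_row(u, v):
    dot = sum(a * b for a, b in zip(u, v))
    nu = math.sqrt(sum(a * a for a in u) + FLOOR)
    nv = math.sqrt(sum(b * b for b in v) + FLOOR)
    return dot / (nu * nv)


def cosine_align_loop(hs, ht, mask=None):
    """Mean over (unmasked) token rows of 1 - cos."""
    H_s = hs.reshape(-1, hs.shape[-1])
    H_t = ht.reshape(-1, ht.shape[-1])
    m = mask.reshape(-1) if mask is not None else [1] * H_s.shape[0]
    total, count = 0.0, 0
    for n in range(H_s.shape[0]):
        if not m[n]:
            continue
        total += 1.0 - cosine_row(list(H_s[n]), list(H_t[n]))
        count += 1
    return total / count if count else 0.0


def mse_loop(a, b):
    fa, fb = a.reshape(-1), b.reshape(-1)
    return sum((x - y) ** 2 for x, y in zip(fa, fb)) / fa.shape[0]


def layer_loss_loop(s_hidden, t_hidden, s_attn, t_attn, layer_map, layer_lambdas=None,
                    projection=None):
    """sum_l lambda_l (MSE(h_s Wp, h_t,g(l)) + MSE(a_s, a_t,g(l))); no padding."""
    total = 0.0
    for l, gl in sorted(layer_map.items()):
        lam = 1.0 if layer_lambdas is None else layer_lambdas[l - 1]
        hs = s_hidden[l]
        if projection is not None:
            hs = hs @ projection
        total += lam * (mse_loop(hs, t_hidden[gl]) + mse_loop(s_attn[l - 1], t_attn[gl - 1]))
    return total


def kl_row(p, q):
    return sum(a * (math.log(a + FLOOR) - math.log(b + FLOOR)) for a, b in zip(p, q))


def compact_loss_loop(s_hidden, t_hidden, s_attn, t_attn, layer_map):
    """Per layer: mean(1-cos) over rows + mean KL over head x row attention rows."""
    total = 0.0
    for l, gl in sorted(layer_map.items()):
        total += cosine_align_loop(s_hidden[l], t_hidden[gl])
        a_s = s_attn[l - 1].reshape(-1, s_attn[l - 1].shape[-1])
        a_t = t_attn[gl - 1].reshape(-1, t_attn[gl - 1].shape[-1])
        kl = 0.0
        for n in range(a_s.shape[0]):
            kl += kl_row(list(a_s[n]), list(a_t[n]))
        total += kl / a_s.shape[0]
    return total
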