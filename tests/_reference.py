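"""Independent reference implementations used as test oracles.

Everything here is written as straight-line transcriptions of the
underlying formulas (nested loops, explicit per-step algebra), kept
deliberately separate from the package's vectorized implementations.
"""

from __future__ import annotations

import numpy as np


class RecordingRng:
    """Wraps a numpy Generator, recording every uniform draw in order."""

    def __init__(self, seed: int):
        self._rng = np.random.default_rng(seed)
        self.draws: list[float] = []

    def random(self, size=None):
        out = self._rng.random(size)
        if size is None:
            self.draws.append(float(out))
        else:
            self.draws.extend(np.asarray(out).ravel().tolist())
        return out


class DrawQueue:
    """Replays a recorded draw sequence."""

    def __init__(self, draws):
        self._draws = list(draws)
        self._pos = 0

    def next(self) -> float:
        value = self._draws[self._pos]
        self._pos += 1
        return value

    def take(self, count: int) -> list[float]:
        return [self.next() for _ in range(count)]


def hbo_reference_run(objective, lower, upper, n_badgers, beta, density_constant,
                      n_iterations, draws):
    """Line-by-line transcription of the honey badger update equations.

    Consumes the recorded uniform draws in the documented order and
    returns (initial positions, list of candidate positions in evaluation
    order, final prey position, prey fitness history).
    """
    queue = DrawQueue(draws)
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    dim = lower.size

    positions = np.empty((n_badgers, dim))
    for j in range(n_badgers):
        for k in range(dim):
            r1 = queue.next()
            positions[j, k] = lower[k] + r1 * (upper[k] - lower[k])
    fitness = np.array([objective(p) for p in positions])
    best = int(np.argmin(fitness))
    prey = positions[best].copy()
    prey_fitness = float(fitness[best])
    history = [prey_fitness]

    candidates = []
    for it in range(1, n_iterations + 1):
        phi = density_constant * np.exp(-it / n_iterations)
        for j in range(n_badgers):
            y_j = positions[j].copy()
            d_vec = prey - y_j
            coin = queue.next()
            if coin < 0.5:  # digging
                r2 = queue.next()
                y_next = positions[(j + 1) % n_badgers]
                ss = float(np.sum((y_j - y_next) ** 2))
                d_sq = float(np.sum((prey - y_j) ** 2))
                intensity = r2 * ss / (4.0 * np.pi * d_sq + 1e-12)
                r3 = queue.next()
                flag = 1 if r3 <= 0.5 else -1
                r4 = queue.next()
                r5 = queue.next()
                r6 = queue.next()
                candidate = (
                    prey
                    + flag * beta * intensity * prey
                    + flag * r4 * phi * d_vec
                    * np.cos(2 * np.pi * r5) * (1 - np.cos(2 * np.pi * r6))
                )
            else:  # honey
                r3 = queue.next()
                flag = 1 if r3 <= 0.5 else -1
                r7 = queue.next()
                candidate = prey + flag * r7 * phi * d_vec
            candidate = np.minimum(np.maximum(candidate, lower), upper)
            candidates.append(candidate.copy())
            value = float(objective(candidate))
            if value < fitness[j]:
                positions[j] = candidate
                fitness[j] = value
            if value < prey_fitness:
                prey = candidate.copy()
                prey_fitness = value
        history.append(prey_fitness)
    return positions, candidates, prey, history


def conv_loops(x, weights, bias, stride=1, padding=0, relu=True):
    """Six-nested-loop standard convolution on (H, W, Cin)."""
    kh, kw, c_in, c_out = weights.shape
    if padding:
        x = np.pad(x, ((padding, padding), (padding, padding), (0, 0)))
    h, w, _ = x.shape
    ho = (h - kh) // stride + 1
    wo = (w - kw) // stride + 1
    out = np.zeros((ho, wo, c_out))
    for i in range(ho):
        for j in range(wo):
            for s in range(c_out):
                acc = bias[s]
                for a in range(kh):
                    for b in range(kw):
                        for c in range(c_in):
                            acc += x[i * stride + a, j * stride + b, c] * weights[a, b, c, s]
                out[i, j, s] = max(acc, 0.0) if relu else acc
    return out


def depthwise_loops(x, weights, bias, stride=1, padding=0, relu=True):
    """Per-channel spatial convolution, loop transcription."""
    kh, kw, c = weights.shape
    if padding:
        x = np.pad(x, ((padding, padding), (padding, padding), (0, 0)))
    h, w, _ = x.shape
    ho = (h - kh) // stride + 1
    wo = (w - kw) // stride + 1
    out = np.zeros((ho, wo, c))
    for i in range(ho):
        for j in range(wo):
            for ch in range(c):
                acc = bias[ch]
                for a in range(kh):
                    for b in range(kw):
                        acc += x[i * stride + a, j * stride + b, ch] * weights[a, b, ch]
                out[i, j, ch] = max(acc, 0.0) if relu else acc
    return out


def max_pool_loops(x, window, stride):
    h, w, c = x.shape
    ho = (h - window) // stride + 1
    wo = (w - window) // stride + 1
    out = np.zeros((ho, wo, c))
    for i in range(ho):
        for j in range(wo):
            for ch in range(c):
                out[i, j, ch] = x[
                    i * stride : i * stride + window,
                    j * stride : j * stride + window,
                    ch,
                ].max()
    return out


def global_he_levels(levels, n_bins):
    """Canonical global histogram equalization on integer levels."""
    hist = np.bincount(levels.ravel(), minlength=n_bins)
    cdf = np.cumsum(hist)
    nonzero = np.flatnonzero(hist)
    if nonzero.size <= 1:
        return levels.copy()
    cdf_min = cdf[nonzero[0]]
    total = cdf[-1]
    lut = np.rint((cdf - cdf_min) / (total - cdf_min) * (n_bins - 1)).astype(int)
    return lut[levels]


def anfis_five_layer(x, centers, widths, consequents):
    """Layer-by-layer Sugeno evaluation for one input vector.

    Layers: fuzzify each input against each MF, per-rule product strength
    over the full grid, normalization, per-rule first-order consequent,
    weighted sum per output.
    """
    import itertools

    d, m = centers.shape
    degrees = [
        [np.exp(-((x[i] - centers[i, j]) ** 2) / (2 * widths[i, j] ** 2))
         for j in range(m)]
        for i in range(d)
    ]
    rules = list(itertools.product(range(m), repeat=d))
    strengths = []
    for rule in rules:
        w = 1.0
        for i, j in enumerate(rule):
            w *= degrees[i][j]
        strengths.append(w)
    total = sum(strengths)
    if total < 1e-300:
        norm = [1.0 / len(rules)] * len(rules)
    else:
        norm = [s / total for s in strengths]
    n_out = consequents.shape[0]
    scores = np.zeros(n_out)
    for k in range(n_out):
        for r in range(len(rules)):
            f = consequents[k, r, -1]
            for i in range(d):
                f += consequents[k, r, i] * x[i]
            scores[k] += norm[r] * f
    return scores


def rank_auc(labels, scores):
    """Mann-Whitney AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))
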