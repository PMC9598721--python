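"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written as slow, straight-line code with
its own arithmetic (explicit loops, no shared helpers from the package),
so that agreement with the package is a genuine cross-check.
"""

from __future__ import annotations

import math

import numpy as np


# -- descriptors -----------------------------------------------------------

def sector_of_offset(di: int, dj: int, p: int) -> int:
    """Angular bin of an offset, computed via a cumulative-angle scan
    rather than floor division."""
    angle = math.atan2(-di, dj)
    if angle < 0:
        angle += 2.0 * math.pi
    width = 2.0 * math.pi / p
    n = 0
    while (n + 1) * width <= angle + 1e-12 and n < p - 1:
        n += 1
    return n


def avn_code_at(img: np.ndarray, i: int, j: int, p: int, radius: int) -> int:
    """Sector-averaged code of one pixel by explicit offset loops, in exact
    rational arithmetic so threshold ties are decided correctly."""
    from fractions import Fraction

    sums = [0] * p
    counts = [0] * p
    for di in range(-radius, radius + 1):
        for dj in range(-radius, radius + 1):
            if di == 0 and dj == 0:
                continue
            n = sector_of_offset(di, dj, p)
            sums[n] += int(img[i + di, j + dj])
            counts[n] += 1
    means = [Fraction(s, c) for s, c in zip(sums, counts)]
    mu = sum(means, Fraction(0)) / p
    code = 0
    for n in range(p):
        if means[n] >= mu:
            code += 2 ** n
    return code


def bilinear(img: np.ndarray, r: float, c: float) -> float:
    r0, c0 = int(math.floor(r)), int(math.floor(c))
    r1, c1 = min(r0 + 1, img.shape[0] - 1), min(c0 + 1, img.shape[1] - 1)
    fr, fc = r - r0, c - c0
    return ((1 - fr) * (1 - fc) * img[r0, c0] + (1 - fr) * fc * img[r0, c1]
            + fr * (1 - fc) * img[r1, c0] + fr * fc * img[r1, c1])


def classic_code_at(img: np.ndarray, i: int, j: int, p: int, radius: float,
                    threshold: float = 1.0) -> int:
    """Classic LBP code of one pixel: p circle samples starting at angle 0,
    counter-clockwise, bilinear interpolation, explicit accumulation."""
    code = 0
    for n in range(p):
        angle = 2.0 * math.pi * n / p
        dc = radius * math.cos(angle)
        dr = -radius * math.sin(angle)
        if abs(dc - round(dc)) < 1e-9:
            dc = round(dc)
        if abs(dr - round(dr)) < 1e-9:
            dr = round(dr)
        sample = bilinear(img.astype(float), i + dr, j + dc)
        if sample - float(img[i, j]) >= threshold:
            code += 2 ** n
    return code


def code_map_bruteforce(img: np.ndarray, p: int, radius: int,
                        variant: str, threshold: float = 1.0) -> np.ndarray:
    h, w = img.shape
    out = np.zeros((h - 2 * radius, w - 2 * radius), dtype=int)
    for i in range(radius, h - radius):
        for j in range(radius, w - radius):
            if variant == "avn":
                out[i - radius, j - radius] = avn_code_at(img, i, j, p, radius)
            else:
                out[i - radius, j - radius] = classic_code_at(
                    img, i, j, p, radius, threshold)
    return out


# -- Fuzzy ARTMAP ----------------------------------------------------------

def fam_train_oracle(X, y, rho=1.0, alpha=0.001, beta=0.8, epsilon=0.001,
                     epochs=5):
    """Straight-line transliteration of the FAM training procedure.

    Returns (weights list, category label list).  Complement coding,
    choice-ranked search, vigilance, match tracking, convex update, new
    category on exhausted search; rho capped just below 1.
    """
    rho_base = min(rho, 1.0 - 1e-9)
    d = len(X[0])
    weights: list[list[float]] = []
    cats: list[int] = []
    seen: set[int] = set()
    for _ in range(epochs):
        for a, label in zip(X, y):
            ai = [float(v) for v in a] + [1.0 - float(v) for v in a]
            if int(label) not in seen:
                weights.append(list(ai))
                cats.append(int(label))
                seen.add(int(label))
                continue
            ts = []
            for wj in weights:
                overlap = sum(min(x, w) for x, w in zip(ai, wj))
                ts.append(overlap / (alpha + sum(wj)))
            order = sorted(range(len(ts)), key=lambda k: (-ts[k], k))
            rho_now = rho_base
            done = False
            for jj in order:
                overlap = sum(min(x, w) for x, w in zip(ai, weights[jj]))
                match = overlap / float(d)
                if match < rho_now:
                    continue
                if cats[jj] == int(label):
                    weights[jj] = [beta * min(x, w) + (1 - beta) * w
                                   for x, w in zip(ai, weights[jj])]
                    done = True
                    break
                rho_now = match + epsilon
            if not done:
                weights.append(list(ai))
                cats.append(int(label))
    return weights, cats


def fam_predict_oracle(weights, cats, a, alpha=0.001):
    ai = [float(v) for v in a] + [1.0 - float(v) for v in a]
    best_j, best_t = 0, -1.0
    for j, wj in enumerate(weights):
        overlap = sum(min(x, w) for x, w in zip(ai, wj))
        t = overlap / (alpha + sum(wj))
        if t > best_t:
            best_j, best_t = j, t
    return cats[best_j]


# -- retrieval metrics -----------------------------------------------------

def metrics_oracle(db_labels, query_results, query_labels):
    """Per-query precision/recall by explicit set intersection counting.

    ``query_results`` is a list of retrieved index lists.
    """
    precisions, recalls = [], []
    for retrieved, ql in zip(query_results, query_labels):
        relevant = {i for i, lbl in enumerate(db_labels) if lbl == ql}
        hit = len(set(retrieved) & relevant)
        precisions.append(hit / len(retrieved))
        recalls.append(hit / len(relevant))
    return precisions, recalls


# -- shared synthetic scenario --------------------------------------------

def overlapping_feature_set(rng, n_per_class=30, spread=0.13):
    """Three partially overlapping Gaussian classes in [0,1]^4 — the
    regime in which FAM category proliferation appears."""
    centers = np.array([[0.2, 0.2, 0.8, 0.5],
                        [0.8, 0.3, 0.2, 0.5],
                        [0.5, 0.8, 0.5, 0.2]])
    X, y = [], []
    for c in range(3):
        X.append(np.clip(centers[c] + rng.normal(0, spread, (n_per_class, 4)),
                         0, 1))
        y.append(np.full(n_per_class, c))
    return np.vstack(X), np.concatenate(y)
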