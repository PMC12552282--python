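"""Independent brute-force oracles used by the tests.

These deliberately share no code with the package: the STD filter and the
five-lowest-circles estimate are evaluated by direct enumeration of every
window, and Gwet's AC2 is a second, loop-based transcription of the published
estimator.
"""

import math

import numpy as np


def in_disk(dr: int, dc: int, radius: float) -> bool:
    return dr * dr + dc * dc <= radius * radius + 1e-9


def brute_std_filter(pixels, mask, radius):
    """Sample STD (ddof=1) over every complete circular window, else NaN."""
    h, w = pixels.shape
    r = int(math.floor(radius + 1e-9))
    out = np.full((h, w), np.nan)
    for i in range(h):
        for j in range(w):
            vals = []
            complete = True
            for dr in range(-r, r + 1):
                for dc in range(-r, r + 1):
                    if not in_disk(dr, dc, radius):
                        continue
                    ii, jj = i + dr, j + dc
                    if not (0 <= ii < h and 0 <= jj < w) or not mask[ii, jj]:
                        complete = False
                        break
                    vals.append(pixels[ii, jj])
                if not complete:
                    break
            if complete:
                out[i, j] = np.std(vals, ddof=1)
    return out


def brute_std_min(noise_map, region_mask, diameter, k):
    """Direct enumeration of candidate circles and the k-lowest mean."""
    h, w = noise_map.shape
    radius = diameter / 2.0
    r = int(math.floor(radius + 1e-9))
    defined = np.isfinite(noise_map) & region_mask
    cands = []
    for i in range(h):
        for j in range(w):
            vals = []
            complete = True
            for dr in range(-r, r + 1):
                for dc in range(-r, r + 1):
                    if not in_disk(dr, dc, radius):
                        continue
                    ii, jj = i + dr, j + dc
                    if not (0 <= ii < h and 0 <= jj < w) or not defined[ii, jj]:
                        complete = False
                        break
                    vals.append(noise_map[ii, jj])
                if not complete:
                    break
            if complete:
                cands.append((float(np.mean(vals)), i, j))
    cands.sort()
    assert len(cands) >= k
    return float(np.mean([c[0] for c in cands[:k]]))


def gwet_ac2_oracle(scores, categories, weights):
    """Loop-based transcription of Gwet's multi-rater weighted AC estimator.

    scores: items x raters array with NaN for missing; categories: ordered
    list; weights: q x q list of lists.
    """
    cats = list(categories)
    q = len(cats)
    counts = []
    for row in scores:
        c = [0.0] * q
        for v in row:
            if not (isinstance(v, float) and math.isnan(v)):
                c[cats.index(v)] += 1.0
        counts.append(c)
    counts = [c for c in counts if sum(c) >= 1]
    n = len(counts)

    # observed weighted agreement over items with >= 2 raters
    pa_terms = []
    for c in counts:
        ri = sum(c)
        if ri < 2:
            continue
        rstar = [sum(weights[k][l] * c[l] for l in range(q)) for k in range(q)]
        pa_terms.append(sum(c[k] * (rstar[k] - 1.0) for k in range(q)) / (ri * (ri - 1.0)))
    pa = sum(pa_terms) / len(pa_terms)

    # chance agreement from overall propensities
    pi = [sum(c[k] / sum(c) for c in counts) / n for k in range(q)]
    tw = sum(sum(wrow) for wrow in weights)
    pe = tw * sum(p * (1.0 - p) for p in pi) / (q * (q - 1.0))
    return (pa - pe) / (1.0 - pe)


def make_copy_table(rng, n_items=10, n_raters=3, copy_prob=0.8, levels=(1, 2, 3, 4, 5)):
    """Seeded ratings table: each rater copies the item's base score w.p. copy_prob."""
    base = rng.choice(levels, size=n_items)
    scores = np.empty((n_items, n_raters), dtype=float)
    for i in range(n_items):
        for j in range(n_raters):
            if rng.random() < copy_prob:
                scores[i, j] = base[i]
            else:
                scores[i, j] = rng.choice(levels)
    return scores
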