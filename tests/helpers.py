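"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written as plain double loops / naive
recursion, sharing no code path with the package implementation.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
import pandas as pd

import eventrsa as er
from eventrsa.simulate import _location_schedule


def brute_cosine(u, v) -> float:
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    return float(np.dot(u, v) / (math.sqrt(np.dot(u, u)) * math.sqrt(np.dot(v, v))))


def brute_levenshtein(a: str, b: str) -> int:
    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> int:
        if i == 0:
            return j
        if j == 0:
            return i
        return min(
            rec(i - 1, j) + 1,
            rec(i, j - 1) + 1,
            rec(i - 1, j - 1) + (a[i - 1] != b[j - 1]),
        )

    return rec(len(a), len(b))


def brute_spearman_upper(a: np.ndarray, b: np.ndarray) -> float:
    """Rank-then-Pearson over the strictly-upper-triangle cells."""
    n = a.shape[0]
    cells_a, cells_b = [], []
    for i in range(n):
        for j in range(i + 1, n):
            cells_a.append(a[i, j])
            cells_b.append(b[i, j])

    def midranks(x):
        order = sorted(range(len(x)), key=lambda k: x[k])
        ranks = [0.0] * len(x)
        i = 0
        while i < len(x):
            j = i
            while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
                j += 1
            for k in range(i, j + 1):
                ranks[order[k]] = (i + j) / 2 + 1
            i = j + 1
        return ranks

    ra, rb = midranks(cells_a), midranks(cells_b)
    ma, mb = sum(ra) / len(ra), sum(rb) / len(rb)
    num = sum((x - ma) * (y - mb) for x, y in zip(ra, rb))
    den = math.sqrt(sum((x - ma) ** 2 for x in ra) * sum((y - mb) ** 2 for y in rb))
    return num / den


def brute_fmri_matrix(patterns, entities, locations):
    """Entity-pair mean cosine with same-location exclusion, double loop."""
    labels = sorted(set(entities))
    n = len(labels)
    out = np.ones((n, n))
    for a in range(n):
        for b in range(n):
            if a == b:
                continue
            vals = []
            for i in range(len(entities)):
                for j in range(len(entities)):
                    if (
                        entities[i] == labels[a]
                        and entities[j] == labels[b]
                        and locations[i] != locations[j]
                    ):
                        vals.append(brute_cosine(patterns[i], patterns[j]))
            out[a, b] = sum(vals) / len(vals)
    return labels, out


def brute_identity(patterns, entities, locations) -> float:
    per_entity = []
    for lab in sorted(set(entities)):
        vals = []
        idx = [i for i, e in enumerate(entities) if e == lab]
        for ii, i in enumerate(idx):
            for j in idx[ii + 1 :]:
                if locations[i] != locations[j]:
                    vals.append(brute_cosine(patterns[i], patterns[j]))
        per_entity.append(sum(vals) / len(vals))
    return sum(per_entity) / len(per_entity)


def brute_location(patterns, entities, locations) -> float:
    per_loc = []
    for lab in sorted(set(locations)):
        vals = []
        idx = [i for i, l in enumerate(locations) if l == lab]
        for ii, i in enumerate(idx):
            for j in idx[ii + 1 :]:
                if entities[i] != entities[j]:
                    vals.append(brute_cosine(patterns[i], patterns[j]))
        per_loc.append(sum(vals) / len(vals))
    return sum(per_loc) / len(per_loc)


def make_table(
    n_entities: int,
    n_runs: int,
    n_locations: int = 4,
    seed: int = 0,
    subject: str = "sub-01",
    isi: float = 8.5,
) -> er.TrialTable:
    """Counterbalanced single-subject trial table (no time series)."""
    rng = np.random.default_rng(seed)
    sched = _location_schedule(rng, n_entities, n_runs, n_locations)
    labels = [f"e{i:02d}" for i in range(n_entities)]
    rows = []
    for r in range(n_runs):
        order = rng.permutation(n_entities)
        for k, e in enumerate(order):
            rows.append(
                {
                    "subject": subject,
                    "run": r + 1,
                    "onset": 2.0 + k * isi,
                    "entity": labels[e],
                    "category": "A" if e < n_entities // 2 else "B",
                    "location": int(sched[e, r]),
                    "size": 1,
                    "mirrored": False,
                }
            )
    return er.TrialTable(pd.DataFrame(rows), locations=tuple(range(1, n_locations + 1)))


def tiny_identity_location_fixture(seed: int = 7):
    """3 entities x 2 runs; locations chosen so every entity and every
    occupied location has an admissible pair."""
    rows = []
    plan = {"ea": (1, 2), "eb": (2, 3), "ec": (3, 1)}
    for r in (1, 2):
        for k, (ent, locs) in enumerate(sorted(plan.items())):
            rows.append(
                {
                    "subject": "sub-01",
                    "run": r,
                    "onset": 2.0 + k * 8.5,
                    "entity": ent,
                    "category": "A",
                    "location": locs[r - 1],
                    "size": 1,
                    "mirrored": False,
                }
            )
    tt = er.TrialTable(pd.DataFrame(rows))
    rng = np.random.default_rng(seed)
    rps = er.ResponsePatternSet(rng.standard_normal((len(tt), 5)), (2.0, 8.0))
    return rps, tt
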