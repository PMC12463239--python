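"""Shared fixtures and independent oracle helpers for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from maedeconv.io_tables import PeptideRecord
from maedeconv.simulate import SimulationConfig, simulate_dataset


def rec(
    sequence: str,
    cell_line: str = "c1",
    replicate: str = "r1",
    spectral_count: int = 1,
    protein_id: str | None = None,
    start: int | None = None,
    end: int | None = None,
    intensity: float | None = None,
) -> PeptideRecord:
    """Terse record constructor for tests."""
    return PeptideRecord(
        sequence=sequence,
        cell_line=cell_line,
        replicate=replicate,
        spectral_count=spectral_count,
        protein_id=protein_id,
        start=start,
        end=end,
        intensity=intensity,
    )


@pytest.fixture(scope="session")
def clean_dataset():
    """Zero-dropout, zero-contaminant family peptidome (fixed seed)."""
    cfg = SimulationConfig(seed=1, replicate_dropout=0.0, contaminant_fraction=0.0)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def noisy_dataset():
    """Default-noise family peptidome (dropout and contaminants on)."""
    return simulate_dataset(SimulationConfig(seed=7))


# --- independent oracles ----------------------------------------------------


def overlap_merges(u: str, v: str, min_overlap: int) -> set[str]:
    """All superstrings obtainable by one admissible merge of u and v.

    Containment, or any suffix/prefix identity of length >= min_overlap,
    in either direction.  Independent of the implementation's placement
    heuristics: *every* admissible overlap is enumerated.
    """
    out: set[str] = set()
    if v in u:
        out.add(u)
    if u in v:
        out.add(v)
    for k in range(min_overlap, min(len(u), len(v))):
        if u[-k:] == v[:k]:
            out.add(u + v[k:])
        if v[-k:] == u[:k]:
            out.add(v + u[k:])
    return out


def exhaustive_superstrings(seqs: tuple[str, ...], min_overlap: int) -> set[str]:
    """All single superstrings reachable by any merge order (memoized DFS)."""
    memo: dict[frozenset[str], set[str]] = {}

    def go(state: frozenset[str]) -> set[str]:
        if len(state) == 1:
            return set(state)
        if state in memo:
            return memo[state]
        results: set[str] = set()
        items = sorted(state)
        for a, b in itertools.combinations(items, 2):
            for merged in overlap_merges(a, b, min_overlap):
                nxt = frozenset(s for s in state if s not in (a, b)) | {merged}
                results |= go(nxt)
        memo[state] = results
        return results

    return go(frozenset(seqs))


def brute_force_centroid_linkage(data: np.ndarray, dist) -> list[tuple[int, int, float]]:
    """From-scratch agglomerative centroid linkage for the clustering oracle.

    Re-derives every centroid as the mean of its member rows at every step
    and scans all cluster pairs; ties broken by the sorted pair of minimum
    original row indices, then cluster ids.  Written independently of the
    implementation (no distance caching, no incremental updates).
    """
    n = data.shape[0]
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    merges: list[tuple[int, int, float]] = []
    for step in range(n - 1):
        candidates = []
        ids = sorted(members)
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                ca = data[members[a]].mean(axis=0)
                cb = data[members[b]].mean(axis=0)
                d = dist(ca, cb)
                ra, rb = min(members[a]), min(members[b])
                candidates.append((d, min(ra, rb), max(ra, rb), a, b))
        d, _ra, _rb, a, b = min(candidates)
        members[n + step] = members.pop(a) + members.pop(b)
        merges.append((a, b, max(d, 0.0)))
    return merges


def exhaustive_offset_alignment(
    seqs: list[str], max_len: int, matrix
) -> tuple[float, list[int]]:
    """Globally optimal offset vector by exhaustive search (width <= max_len).

    Enumerates every offset assignment with all offsets in
    [0, max_len - len] and minimum offset 0, scoring sum-of-pairs directly
    from the padded rows.
    """
    ranges = [range(0, max_len - len(s) + 1) for s in seqs]
    best_score, best_offsets = -np.inf, None
    for offsets in itertools.product(*ranges):
        if min(offsets) != 0:
            continue
        width = max(o + len(s) for o, s in zip(offsets, seqs))
        score = 0.0
        for col in range(width):
            residues = [
                s[col - o]
                for o, s in zip(offsets, seqs)
                if 0 <= col - o < len(s)
            ]
            for i in range(len(residues)):
                for j in range(i + 1, len(residues)):
                    score += matrix[residues[i]][residues[j]]
        if score > best_score:
            best_score, best_offsets = score, list(offsets)
    return best_score, best_offsets


def random_overlapping_component(
    rng: np.random.Generator, min_overlap: int = 5, max_peptides: int = 6
) -> tuple[str, list[tuple[int, int]]]:
    """A random true span plus peptide intervals chained by >= min_overlap.

    Intervals cover the span completely and consecutive intervals overlap
    by at least ``min_overlap`` residues, so all merge orders must
    reconstruct the span.
    """
    letters = np.array(sorted("ACDEFGHIKLMNPQRSTVWY"))
    span_len = int(rng.integers(14, 26))
    span = "".join(rng.choice(letters, size=span_len))
    k = int(rng.integers(2, max_peptides + 1))
    intervals = []
    start = 0
    for i in range(k):
        remaining = k - i - 1
        max_end = span_len if remaining == 0 else span_len - 1
        lo_end = start + max(8, min_overlap)
        if remaining == 0:
            end = span_len
        else:
            end = int(rng.integers(min(lo_end, max_end), max_end + 1))
        intervals.append((start, end))
        if remaining == 0:
            break
        # next start keeps >= min_overlap overlap with this interval
        next_max = end - min_overlap
        start = int(rng.integers(start + 1, max(next_max, start + 1) + 1))
        start = min(start, next_max)
    intervals[-1] = (intervals[-1][0], span_len)
    return span, intervals
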