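"""Small helpers for half-open genomic intervals on a single chromosome.

Intervals are (start, end) pairs with end > start, 0-based half-open.
"""

from __future__ import annotations


def merge(intervals):
    """Sort and merge overlapping or adjacent intervals."""
    out = []
    for start, end in sorted(intervals):
        if out and start <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], end))
        else:
            out.append((start, end))
    return out


def subtract(intervals, holes):
    """Remove ``holes`` from ``intervals``; both need not be sorted."""
    holes = merge(holes)
    out = []
    for start, end in merge(intervals):
        cursor = start
        for h_start, h_end in holes:
            if h_end <= cursor or h_start >= end:
                continue
            if h_start > cursor:
                out.append((cursor, min(h_start, end)))
            cursor = max(cursor, h_end)
            if cursor >= end:
                break
        if cursor < end:
            out.append((cursor, end))
    return out


def intersect(a, b):
    """Pairwise intersection of two interval sets."""
    out = []
    for a_start, a_end in merge(a):
        for b_start, b_end in merge(b):
            start, end = max(a_start, b_start), min(a_end, b_end)
            if end > start:
                out.append((start, end))
    return out


def total_length(intervals):
    return sum(end - start for start, end in merge(intervals))


def overlap_length(a_start, a_end, b_start, b_end):
    return max(0, min(a_end, b_end) - max(a_start, b_start))
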