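"""Independent brute-force oracles used to cross-check the implementation.

These deliberately share no code with the package: substring scans, quadratic
overlap checks, per-read exhaustive assignment, direct Breslow partial
likelihood, hand product-limit and hand BH.
"""

from __future__ import annotations

import math

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def rc(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def brute_hits(genome: dict[str, str], seq: str) -> list[tuple[str, int, str]]:
    """Every exact occurrence on both strands, (chrom, start, + before -) order.

    A position where the sequence equals its own reverse complement counts once
    (forward), matching the documented convention.
    """
    rseq = rc(seq)
    hits = []
    for chrom in sorted(genome):
        contig = genome[chrom].upper()
        L = len(seq)
        for i in range(len(contig) - L + 1):
            window = contig[i : i + L]
            if window == seq:
                hits.append((chrom, i, "+"))
            if window == rseq and not (rseq == seq and window == seq):
                hits.append((chrom, i, "-"))
    return hits


def brute_filter(alignments, intervals: dict[str, list[tuple[int, int]]], mito=None):
    """Quadratic >=1 bp overlap check; returns (retained, removed)."""
    retained, removed = [], []
    for aln in alignments:
        iv = aln.interval
        hit = mito is not None and iv.chrom == mito
        for s, e in intervals.get(iv.chrom, []):
            if iv.start < e and s < iv.end:
                hit = True
                break
        (removed if hit else retained).append(aln)
    return retained, removed


def brute_count(alignments, entries, min_overlap=15, frac=0.80, min_mapq=1):
    """Exhaustive per-read overlap computation and argmax assignment.

    ``entries`` are (accession, chrom, start, end) tuples. Returns
    {(accession, sample): count}.
    """
    counts: dict[tuple[str, str], int] = {}
    for aln in alignments:
        if not aln.is_primary or aln.mapq < min_mapq or aln.read_length <= 0:
            continue
        need = max(min_overlap, math.ceil(round(frac * aln.read_length, 9)))
        best = None
        for acc, chrom, s, e in entries:
            if chrom != aln.interval.chrom:
                continue
            ov = min(e, aln.interval.end) - max(s, aln.interval.start)
            if ov < need:
                continue
            key = (-ov, chrom, s, acc)
            if best is None or key < best[0]:
                best = (key, acc)
        if best is not None:
            k = (best[1], aln.sample_id)
            counts[k] = counts.get(k, 0) + 1
    return counts


def breslow_loglik(times, events, x, beta):
    """Breslow partial log-likelihood for a single covariate vector."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    x = np.asarray(x, float)
    eta = beta * x
    ll = 0.0
    for i in range(len(times)):
        if events[i]:
            at_risk = times >= times[i]
            ll += eta[i] - np.log(np.sum(np.exp(eta[at_risk])))
    return ll


def breslow_loglik_multi(times, events, X, beta):
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    X = np.asarray(X, float)
    eta = X @ np.asarray(beta, float)
    ll = 0.0
    for i in range(len(times)):
        if events[i]:
            at_risk = times >= times[i]
            ll += eta[i] - np.log(np.sum(np.exp(eta[at_risk])))
    return ll


def grid_maximize_beta(times, events, x, lo=-5.0, hi=5.0, tol=1e-6):
    """Golden-section maximization of the 1-covariate Breslow likelihood."""
    phi = (math.sqrt(5) - 1) / 2
    a, b = lo, hi
    c, d = b - phi * (b - a), a + phi * (b - a)
    fc = breslow_loglik(times, events, x, c)
    fd = breslow_loglik(times, events, x, d)
    while b - a > tol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - phi * (b - a)
            fc = breslow_loglik(times, events, x, c)
        else:
            a, c, fc = c, d, fd
            d = a + phi * (b - a)
            fd = breslow_loglik(times, events, x, d)
    return (a + b) / 2


def km_by_hand(times, events):
    """Product-limit estimate: [(time, S(t))] at each distinct event time."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    out = []
    s = 1.0
    for t in sorted(set(times[events == 1])):
        n_at_risk = np.sum(times >= t)
        d = np.sum((times == t) & (events == 1))
        s *= 1.0 - d / n_at_risk
        out.append((t, s))
    return out


def bh_by_hand(pvals):
    """Direct BH step-up: padj_i = min over j: p_(j)>=p_(i) of p_(j)*m/j."""
    p = list(pvals)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [None] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj
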