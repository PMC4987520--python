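"""Independent brute-force reference implementations used as test oracles.

Everything here deliberately avoids the package's vectorised code paths:
Poisson tails are direct PMF summations, interval operations use per-base
membership arrays, and the reference peak caller is a plain-Python rewrite
of the published procedure.
"""

from __future__ import annotations

import math


def pmf_upper_tail(k: int, lam: float) -> float:
    """P(X >= k) for Poisson(lam) by direct summation of upper-tail PMF terms.

    Terms are added from j = k upward until they are negligible relative to
    the running sum (avoids the cancellation of the 1 - lower-tail form).
    """
    if k <= 0:
        return 1.0
    if lam == 0:
        return 0.0
    total = 0.0
    j = k
    while True:
        term = math.exp(-lam + j * math.log(lam) - math.lgamma(j + 1))
        total += term
        j += 1
        if j > lam and (term == 0.0 or term < total * 1e-18):
            break
    return min(1.0, total)


def call_peaks_naive(ip_reads, input_reads, chrom_sizes, window=50, ext=150, alpha=1e-3):
    """Reference window/Poisson caller: returns [(chrom, start, end)] peaks.

    Dedupe on (chrom, pos, strand); extend each read to an ext-long fragment
    in its 3' direction; count fragments per 50-bp window; scale input to IP
    totals with the genome-mean floor; PMF-summation Poisson tails; strict
    P < alpha; a window qualifies when it and both neighbours are
    significant; a maximal significant run containing a qualifying window
    becomes a peak.
    """

    def dedupe(reads):
        seen, out = set(), []
        for r in reads:
            key = (r.chrom, r.pos, r.strand)
            if key not in seen:
                seen.add(key)
                out.append(r)
        return out

    def extend(r):
        if r.strand == "+":
            lo, hi = r.pos, r.pos + ext
        else:
            lo, hi = r.pos + r.length - ext, r.pos + r.length
        return r.chrom, max(0, lo), min(hi, chrom_sizes[r.chrom])

    def window_counts(reads):
        counts = {
            c: [0] * ((length + window - 1) // window) for c, length in chrom_sizes.items()
        }
        for r in reads:
            chrom, lo, hi = extend(r)
            if hi <= lo:
                continue
            for w in range(lo // window, (hi - 1) // window + 1):
                if w < len(counts[chrom]):
                    counts[chrom][w] += 1
        return counts

    ip = dedupe(ip_reads)
    inp = dedupe(input_reads)
    ip_counts = window_counts(ip)
    in_counts = window_counts(inp)
    scale = len(ip) / len(inp)

    n_windows = sum(len(v) for v in in_counts.values())
    floor = sum(sum(v) for v in in_counts.values()) * scale / n_windows

    peaks = []
    for chrom in sorted(chrom_sizes):
        pvals = []
        for k, kin in zip(ip_counts[chrom], in_counts[chrom]):
            lam = max(kin * scale, floor)
            pvals.append(pmf_upper_tail(k, lam))
        sig = [p < alpha for p in pvals]
        qual = [
            0 < i < len(sig) - 1 and sig[i - 1] and sig[i] and sig[i + 1]
            for i in range(len(sig))
        ]
        i = 0
        while i < len(sig):
            if not sig[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(sig) and sig[j + 1]:
                j += 1
            if any(qual[i : j + 1]):
                end = min((j + 1) * window, chrom_sizes[chrom])
                peaks.append((chrom, i * window, end))
            i = j + 1
    return peaks


def per_base_members(intervals, chrom_len):
    """Per-base list of interval indices covering each position (one chromosome)."""
    cover = [[] for _ in range(chrom_len)]
    for idx, iv in enumerate(intervals):
        for pos in range(iv.start, min(iv.end, chrom_len)):
            cover[pos].append(idx)
    return cover


def intersect_naive(a, b, chrom_len):
    """All overlapping pairs between single-chromosome interval lists, with
    the overlap, found via per-base membership arrays."""
    ca = per_base_members(a, chrom_len)
    cb = per_base_members(b, chrom_len)
    pair_bases: dict[tuple[int, int], list[int]] = {}
    for pos in range(chrom_len):
        for i in ca[pos]:
            for j in cb[pos]:
                pair_bases.setdefault((i, j), []).append(pos)
    out = []
    for (i, j), bases in pair_bases.items():
        out.append((i, j, min(bases), max(bases) + 1))
    out.sort(key=lambda t: (t[2], t[3], t[0], t[1]))
    return out


def merge_naive(intervals, chrom_len):
    """Union of intervals via a per-base coverage array."""
    covered = [False] * chrom_len
    for iv in intervals:
        for pos in range(iv.start, min(iv.end, chrom_len)):
            covered[pos] = True
    out = []
    pos = 0
    while pos < chrom_len:
        if covered[pos]:
            start = pos
            while pos < chrom_len and covered[pos]:
                pos += 1
            out.append((start, pos))
        else:
            pos += 1
    return out


def regulatory_domains_naive(tss_list, chrom_len, basal_up, basal_down, max_ext):
    """Per-gene regulatory domains, one chromosome, by explicit neighbour scan.

    Basal: strand-aware [pos-up, pos+down). Extension: each side grows to
    max_ext from the TSS but stops at the midpoint of the gap to the nearest
    neighbouring basal domain on that side.
    """
    basal = {}
    for t in tss_list:
        if t.strand == "-":
            lo, hi = t.pos - basal_down, t.pos + basal_up
        else:
            lo, hi = t.pos - basal_up, t.pos + basal_down
        basal[t.gene_id] = (max(0, lo), min(chrom_len, hi))
    domains = {}
    for t in tss_list:
        b_lo, b_hi = basal[t.gene_id]
        left_neighbors = [basal[o.gene_id][1] for o in tss_list if o.pos < t.pos]
        right_neighbors = [basal[o.gene_id][0] for o in tss_list if o.pos > t.pos]
        left_cap = (max(left_neighbors) + b_lo + 1) // 2 if left_neighbors else 0
        right_cap = (b_hi + min(right_neighbors)) // 2 if right_neighbors else chrom_len
        lo = min(b_lo, max(t.pos - max_ext, left_cap, 0))
        hi = max(b_hi, min(t.pos + max_ext, right_cap, chrom_len))
        domains[t.gene_id] = (max(0, lo), min(chrom_len, hi))
    return domains


def assign_genes_naive(peaks, tss_list, chrom_len, basal_up, basal_down, max_ext):
    """Peak-to-gene map via per-base domain membership (one chromosome)."""
    domains = regulatory_domains_naive(tss_list, chrom_len, basal_up, basal_down, max_ext)
    membership = [[] for _ in range(chrom_len)]
    for gene, (lo, hi) in sorted(domains.items()):
        for pos in range(lo, hi):
            membership[pos].append(gene)
    out = {}
    for i, pk in enumerate(peaks):
        mid = (pk.start + pk.end) // 2
        out[i] = sorted(membership[mid]) if mid < chrom_len else []
    return out


def overlap_counts_naive(sets, chrom_len):
    """Venn membership of the first-named set via per-base boolean arrays."""
    names = list(sets)
    masks = {}
    for name in names:
        mask = [False] * chrom_len
        for iv in sets[name]:
            for pos in range(iv.start, min(iv.end, chrom_len)):
                mask[pos] = True
        masks[name] = mask
    counts = {}
    for region in sets[names[0]]:
        members = [names[0]]
        for other in names[1:]:
            if any(masks[other][pos] for pos in range(region.start, min(region.end, chrom_len))):
                members.append(other)
        key = tuple(members)
        counts[key] = counts.get(key, 0) + 1
    return counts
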