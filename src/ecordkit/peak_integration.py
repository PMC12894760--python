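"""Integrative statistics over peaks, repeats, domains and gene categories.

Connects binding-site intervals to gene-level results: base-pair-level
overlap of peaks with repeat annotation (comparable to the whole-genome
repeat fraction), assignment of each gene to its nearest peak within the
same H3K9me2 domain, per-gene-set domain-overlap proportions, distances to
nearest elements, and a label-permutation bootstrap for category-by-peak-class
enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pyranges as pr

from .genome_model import GeneRecord, GenomicInterval
from .k9me2_domains import K9Domain


@dataclass(frozen=True)
class GenePeakAssignment:
    """A gene tied to its nearest peak within a shared domain."""

    gene_id: str
    peak_id: str
    distance: int
    domain_id: str


@dataclass
class EnrichmentResult:
    """Observed vs label-shuffled counts for one (category, peak class) cell."""

    category: str
    peak_class: str
    observed: int
    null_mean: float
    null_sd: float
    enrichment: float
    p_value: float
    n_shuffles: int
    seed: int | None = None


def _to_ranges(intervals: Sequence[GenomicInterval]) -> pr.PyRanges:
    return pr.PyRanges(pd.DataFrame({
        "Chromosome": [iv.chrom for iv in intervals],
        "Start": [iv.start for iv in intervals],
        "End": [iv.end for iv in intervals],
    }))


def repeat_overlap_fraction(peaks: Sequence[GenomicInterval],
                            repeats: Sequence[GenomicInterval],
                            genome_size: int | None = None,
                            ) -> dict[str, float | dict[str, float]]:
    """Base-pair-level fraction of peak territory covered by repeats.

    Repeats are flattened (unioned) before intersection so self-overlapping
    annotation does not double count.  When ``genome_size`` is given, the
    whole-genome repeat fraction is reported for comparison, along with a
    per-repeat-class breakdown (by interval name).
    """
    if not peaks:
        raise ValueError("empty peak set")
    peak_bp = sum(p.end - p.start for p in peaks)
    result: dict[str, float | dict[str, float]] = {"peak_bp": float(peak_bp)}

    if repeats:
        flat = _to_ranges(repeats).merge()
        overlap = _to_ranges(peaks).intersect(flat)
        overlap_bp = int(overlap.lengths().sum()) if len(overlap) else 0
        repeat_bp = int(flat.lengths().sum())
    else:
        overlap_bp = repeat_bp = 0
    result["fraction"] = overlap_bp / peak_bp
    if genome_size is not None:
        result["genome_fraction"] = repeat_bp / genome_size

    by_class: dict[str, float] = {}
    classes = {r.name for r in repeats if r.name is not None}
    for cls in sorted(classes):
        sub = [r for r in repeats if r.name == cls]
        flat = _to_ranges(sub).merge()
        ov = _to_ranges(peaks).intersect(flat)
        by_class[cls] = (int(ov.lengths().sum()) if len(ov) else 0) / peak_bp
    if by_class:
        result["by_class"] = by_class
    return result


def assign_genes_to_peaks(genes: Sequence[GeneRecord],
                          peaks: Sequence[GenomicInterval],
                          domains: Sequence[K9Domain],
                          ) -> list[GenePeakAssignment]:
    """Assign each gene to the nearest peak inside the same domain.

    The gene is anchored at its TSS and the peak at its summit (midpoint when
    no summit is recorded); a peak belongs to the domain containing its
    summit.  Genes whose TSS lies outside all domains, or inside a peak-free
    domain, are unassigned.  Distance ties go to the leftmost peak.
    """
    dom_by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for d in domains:
        iv = d.interval
        name = iv.name or f"{iv.chrom}:{iv.start}-{iv.end}"
        dom_by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, name))
    for lst in dom_by_chrom.values():
        lst.sort()

    def locate(chrom: str, pos: int) -> str | None:
        lst = dom_by_chrom.get(chrom)
        if not lst:
            return None
        starts = [s for s, _, _ in lst]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i >= 0 and pos < lst[i][1]:
            return lst[i][2]
        return None

    peaks_by_domain: dict[str, list[tuple[int, str]]] = {}
    for j, p in enumerate(peaks):
        dom = locate(p.chrom, p.anchor)
        if dom is not None:
            pid = p.name if p.name is not None else f"peak_{j}"
            peaks_by_domain.setdefault(dom, []).append((p.anchor, pid))
    for lst in peaks_by_domain.values():
        lst.sort()  # leftmost-first gives the tie-break for free

    out: list[GenePeakAssignment] = []
    for g in genes:
        dom = locate(g.chrom, g.tss)
        if dom is None or dom not in peaks_by_domain:
            continue
        best = min(peaks_by_domain[dom],
                   key=lambda t: (abs(t[0] - g.tss), t[0]))
        out.append(GenePeakAssignment(g.gene_id, best[1],
                                      int(abs(best[0] - g.tss)), dom))
    return out


def bootstrap_enrichment(assignments: Sequence[GenePeakAssignment],
                         gene_categories: Mapping[str, str],
                         peak_classes: Mapping[str, str],
                         n_shuffles: int = 1000,
                         seed: int | None = None) -> list[EnrichmentResult]:
    """Permutation bootstrap of gene-category counts per peak class.

    The observed statistic is the count of assigned genes in each
    (category, peak class) cell.  The null redistributes category labels
    uniformly over the supplied gene universe (the keys of
    ``gene_categories``) while holding the gene-to-peak assignments fixed.
    The empirical p-value uses the add-one estimator
    ``(1 + #{null >= observed}) / (1 + n_shuffles)``.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    universe = sorted(gene_categories)
    labels = np.array([gene_categories[g] for g in universe])
    gene_index = {g: i for i, g in enumerate(universe)}

    assigned = [(a.gene_id, peak_classes[a.peak_id]) for a in assignments
                if a.gene_id in gene_index]
    if not assigned:
        return []
    assigned_idx = np.array([gene_index[g] for g, _ in assigned])
    pk = np.array([c for _, c in assigned])
    pclasses = sorted(set(pk))
    categories = sorted(set(labels))

    obs = np.zeros((len(categories), len(pclasses)), dtype=int)
    cat_of = {c: i for i, c in enumerate(categories)}
    pc_of = {c: i for i, c in enumerate(pclasses)}
    for gi, c in zip(assigned_idx, pk):
        obs[cat_of[labels[gi]], pc_of[c]] += 1

    rng = np.random.default_rng(seed)
    null = np.zeros((n_shuffles, len(categories), len(pclasses)), dtype=int)
    pk_idx = np.array([pc_of[c] for c in pk])
    for s in range(n_shuffles):
        perm = rng.permutation(labels)
        shuffled = perm[assigned_idx]
        for ci, cat in enumerate(categories):
            mask = shuffled == cat
            if mask.any():
                null[s, ci] = np.bincount(pk_idx[mask], minlength=len(pclasses))

    results: list[EnrichmentResult] = []
    for ci, cat in enumerate(categories):
        if np.sum(labels == cat) == 0:
            continue
        for pi, pc in enumerate(pclasses):
            nvals = null[:, ci, pi]
            mean = float(nvals.mean())
            ratio = obs[ci, pi] / mean if mean > 0 else np.inf
            p = float((1 + np.sum(nvals >= obs[ci, pi])) / (1 + n_shuffles))
            results.append(EnrichmentResult(cat, pc, int(obs[ci, pi]), mean,
                                            float(nvals.std()), float(ratio),
                                            p, n_shuffles, seed))
    return results


def domain_overlap_proportion(gene_sets: Mapping[str, Sequence[GeneRecord]],
                              domains: Sequence[K9Domain],
                              ) -> dict[str, float | None]:
    """Per gene set, the fraction of genes whose body overlaps any domain.

    Empty sets yield ``None`` (undefined) rather than a number.
    """
    dom_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    tmp: dict[str, list[tuple[int, int]]] = {}
    for d in domains:
        tmp.setdefault(d.interval.chrom, []).append((d.interval.start,
                                                     d.interval.end))
    for chrom, ivs in tmp.items():
        ivs.sort()
        dom_by_chrom[chrom] = (np.array([s for s, _ in ivs]),
                               np.array([e for _, e in ivs]))

    def overlaps(g: GeneRecord) -> bool:
        if g.chrom not in dom_by_chrom:
            return False
        starts, ends = dom_by_chrom[g.chrom]
        return bool(np.any((starts < g.end) & (ends > g.start)))

    out: dict[str, float | None] = {}
    for name, genes in gene_sets.items():
        if len(genes) == 0:
            out[name] = None
        else:
            out[name] = sum(overlaps(g) for g in genes) / len(genes)
    return out


def distance_to_nearest(queries: Sequence[GenomicInterval],
                        targets: Sequence[GenomicInterval]) -> np.ndarray:
    """Edge-to-edge bp distance from each query to its nearest target.

    Zero when overlapping; infinite when the query's chromosome carries no
    target.  Implemented per chromosome with sorted edge arrays.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for t in targets:
        by_chrom.setdefault(t.chrom, []).append((t.start, t.end))
    sorted_edges: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        starts = np.array([s for s, _ in ivs])
        ends = np.array([e for _, e in ivs])
        # running max of ends makes the "nearest preceding end" well defined
        sorted_edges[chrom] = (starts, np.maximum.accumulate(ends))

    out = np.full(len(queries), np.inf)
    for i, q in enumerate(queries):
        if q.chrom not in sorted_edges:
            continue
        starts, cum_ends = sorted_edges[q.chrom]
        j = int(np.searchsorted(starts, q.end, side="left"))
        d_right = starts[j] - q.end if j < len(starts) else np.inf
        d_left = np.inf
        if j > 0:
            # any target left of q.end overlapping q gives distance 0
            d_left = max(q.start - cum_ends[j - 1], 0)
        out[i] = min(d_right, d_left)
    return out
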