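"""Detection of coordinately repressed gene clusters (ECORDs).

The caller walks genes in genomic order (by TSS) and grows maximal runs of
consecutive same-direction differential genes (DEGs).  A run is interrupted
when the next significant gene changes direction (with no fold-change cutoff:
an opposite-direction "breaker" also interrupts), or when the next DEG lies
in a different TAD.  Static and unexpressed genes are skipped without
breaking a run.  Each cluster's static fraction is the count of static genes
whose bodies intersect the cluster span, over statics plus member DEGs.
ECORDs are the clusters passing size and static-fraction thresholds
(>= 4 DEGs and < 50% static genes for bulk data; >= 5 DEGs for sorted cells).

A shuffle null re-labels a random sample of expressed genes as DEGs and
re-runs the walk, giving the probability that clusters of a given size arise
by chance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .genome_model import (DEGRecord, GeneClass, GeneRecord, TadInterval,
                           ValidationError)

UP = "UP"
DOWN = "DOWN"

_DIRECTION = {
    GeneClass.DEG_UP: UP, GeneClass.BREAKER_UP: UP,
    GeneClass.DEG_DOWN: DOWN, GeneClass.BREAKER_DOWN: DOWN,
}


@dataclass
class GeneCluster:
    """A maximal run of consecutive same-direction DEGs within one TAD."""

    cluster_id: str
    chrom: str
    direction: str
    member_deg_ids: list[str]
    start: int  # span: min start over member DEG gene bodies
    end: int    # span: max end over member DEG gene bodies
    tad_id: str
    static_count: int = 0

    @property
    def deg_count(self) -> int:
        return len(self.member_deg_ids)

    @property
    def static_fraction(self) -> float:
        return self.static_count / (self.static_count + self.deg_count)


@dataclass
class Ecord(GeneCluster):
    """A cluster that passed the ECORD thresholds."""

    min_degs: int = 4
    max_static_fraction: float = 0.5


@dataclass
class ProbabilityCurve:
    """Fraction of iterations yielding a qualifying cluster of >= n DEGs."""

    n_values: np.ndarray
    fraction_passing: np.ndarray
    n_iterations: int
    seed: int | None = None


def assign_tads(genes: Sequence[GeneRecord],
                tads: Sequence[TadInterval]) -> dict[str, str]:
    """Assign every gene to a TAD by TSS containment.

    Genes whose TSS falls outside all TADs get a singleton pseudo-TAD (they
    can never cluster with neighbours).  The assignment is total.
    """
    by_chrom: dict[str, list[TadInterval]] = {}
    for t in tads:
        by_chrom.setdefault(t.chrom, []).append(t)
    starts, ends, ids = {}, {}, {}
    for chrom, ts in by_chrom.items():
        ts.sort(key=lambda t: t.start)
        starts[chrom] = np.array([t.start for t in ts])
        ends[chrom] = np.array([t.end for t in ts])
        ids[chrom] = [t.tad_id for t in ts]

    out: dict[str, str] = {}
    for g in genes:
        tad_id = f"__singleton__{g.gene_id}"
        if g.chrom in starts:
            i = int(np.searchsorted(starts[g.chrom], g.tss, side="right")) - 1
            if i >= 0 and g.tss < ends[g.chrom][i]:
                tad_id = ids[g.chrom][i]
        out[g.gene_id] = tad_id
    return out


def _check_sorted(genes: Sequence[GeneRecord]) -> None:
    keys = [(g.chrom, g.start, g.gene_id) for g in genes]
    if keys != sorted(keys):
        raise ValidationError("genes must be sorted by (chrom, start, gene_id)")


def call_clusters(genes: Sequence[GeneRecord],
                  degs: Mapping[str, DEGRecord],
                  tads: Sequence[TadInterval] | None = None,
                  direction_filter: str = "both",
                  tad_assignment: Mapping[str, str] | None = None,
                  ) -> list[GeneCluster]:
    """Walk genes along the linear genome and emit maximal co-directional runs.

    Genes absent from ``degs`` are treated as unexpressed.  Genes present in
    ``degs`` but absent from the annotation are an error.  Every DEG ends up
    in exactly one cluster; runs of length one are kept (filtering is the job
    of :func:`filter_ecords`).
    """
    _check_sorted(genes)
    known = {g.gene_id for g in genes}
    orphans = sorted(set(degs) - known)
    if orphans:
        raise ValidationError(f"DEG table genes absent from annotation: {orphans}")
    if tad_assignment is None:
        tad_assignment = assign_tads(genes, tads or [])

    # walk in TSS order; ties by (start, gene_id)
    ordered = sorted(genes, key=lambda g: (g.chrom, g.tss, g.start, g.gene_id))
    gene_by_id = {g.gene_id: g for g in genes}

    clusters: list[GeneCluster] = []
    cur: GeneCluster | None = None

    def close() -> None:
        nonlocal cur
        if cur is not None:
            clusters.append(cur)
            cur = None

    for g in ordered:
        rec = degs.get(g.gene_id)
        klass = rec.klass if rec is not None else GeneClass.UNEXPRESSED
        if klass in (GeneClass.STATIC, GeneClass.UNEXPRESSED):
            continue  # skipped, never interrupts
        direction = _DIRECTION[klass]
        is_deg = klass in (GeneClass.DEG_UP, GeneClass.DEG_DOWN)
        if not is_deg:
            # significant sub-threshold gene: breaks opposite-direction runs
            # ("no fold-cutoff" rule); same-direction breakers are skippable
            if cur is not None and direction != cur.direction:
                close()
            continue
        tad = tad_assignment[g.gene_id]
        if cur is not None and (direction != cur.direction or tad != cur.tad_id):
            close()
        if cur is None:
            cur = GeneCluster(cluster_id=f"cluster_{len(clusters) + 1}",
                              chrom=g.chrom, direction=direction,
                              member_deg_ids=[], start=g.start, end=g.end,
                              tad_id=tad)
        cur.member_deg_ids.append(g.gene_id)
        cur.start = min(cur.start, g.start)
        cur.end = max(cur.end, g.end)
    close()

    _attach_static_counts(clusters, genes, degs)
    if direction_filter != "both":
        clusters = [c for c in clusters if c.direction == direction_filter]
    return clusters


def _attach_static_counts(clusters: list[GeneCluster],
                          genes: Sequence[GeneRecord],
                          degs: Mapping[str, DEGRecord]) -> None:
    statics: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        rec = degs.get(g.gene_id)
        if rec is not None and rec.klass == GeneClass.STATIC:
            statics.setdefault(g.chrom, []).append((g.start, g.end))
    arr = {c: (np.array([s for s, _ in iv]), np.array([e for _, e in iv]))
           for c, iv in statics.items()}
    for cl in clusters:
        if cl.chrom in arr:
            s, e = arr[cl.chrom]
            cl.static_count = int(np.sum((s < cl.end) & (e > cl.start)))
        else:
            cl.static_count = 0


def static_fraction(cluster: GeneCluster, genes: Sequence[GeneRecord],
                    degs: Mapping[str, DEGRecord]) -> float:
    """Static genes intersecting the cluster span (>= 1 bp) over that count
    plus the member DEG count."""
    count = sum(1 for g in genes
                if g.chrom == cluster.chrom
                and g.start < cluster.end and g.end > cluster.start
                and g.gene_id in degs
                and degs[g.gene_id].klass == GeneClass.STATIC)
    return count / (count + cluster.deg_count)


def filter_ecords(clusters: Iterable[GeneCluster], min_degs: int = 4,
                  max_static_fraction: float = 0.5,
                  strict: bool = True) -> list[Ecord]:
    """Retain clusters with enough DEGs and a low static fraction.

    ``strict`` applies the static-fraction threshold as a strict inequality
    (< 0.5); the inclusive variant (<=) is available for compatibility with
    the looser phrasing of the threshold.
    """
    if min_degs < 1:
        raise ValueError("min_degs must be >= 1")
    out = []
    for c in clusters:
        if c.deg_count < min_degs:
            continue
        sf = c.static_fraction
        if (sf < max_static_fraction) if strict else (sf <= max_static_fraction):
            out.append(Ecord(cluster_id=c.cluster_id, chrom=c.chrom,
                             direction=c.direction,
                             member_deg_ids=list(c.member_deg_ids),
                             start=c.start, end=c.end, tad_id=c.tad_id,
                             static_count=c.static_count, min_degs=min_degs,
                             max_static_fraction=max_static_fraction))
    return out


def curve_from_clusters(clusters: Sequence[GeneCluster], min_n: int = 1,
                        max_n: int = 20,
                        max_static_fraction: float = 0.5,
                        strict: bool = True) -> np.ndarray:
    """Indicator per n: does any cluster have >= n DEGs and a passing static
    fraction?  Non-increasing in n by construction."""
    ns = np.arange(min_n, max_n + 1)
    best = 0
    for c in clusters:
        sf = c.static_fraction
        ok = (sf < max_static_fraction) if strict else (sf <= max_static_fraction)
        if ok:
            best = max(best, c.deg_count)
    return (ns <= best).astype(float)


def shuffle_probability_curve(genes: Sequence[GeneRecord],
                              tads: Sequence[TadInterval],
                              n_deg: int,
                              n_iterations: int,
                              seed: int | None = None,
                              direction_split: float = 1.0,
                              min_n: int = 1, max_n: int = 20,
                              expressed_ids: Sequence[str] | None = None,
                              max_static_fraction: float = 0.5,
                              strict: bool = True) -> ProbabilityCurve:
    """Shuffle null for cluster sizes.

    Per iteration, ``n_deg`` expressed genes are drawn uniformly without
    replacement and labelled DEGs (UP with probability ``direction_split``);
    every other expressed gene is static.  The walk is re-run and, for each
    n, the iteration scores 1 if any cluster has >= n DEGs and a passing
    static fraction.  Fractions are averaged over iterations.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    universe = list(expressed_ids) if expressed_ids is not None \
        else [g.gene_id for g in genes]
    if n_deg > len(universe):
        raise ValueError("n_deg exceeds number of expressed genes")
    rng = np.random.default_rng(seed)
    assignment = assign_tads(genes, tads)

    static_rec = {gid: DEGRecord(gid, 0.0, 0.5, GeneClass.STATIC)
                  for gid in universe}
    acc = np.zeros(max_n - min_n + 1)
    for _ in range(n_iterations):
        chosen = rng.choice(len(universe), size=n_deg, replace=False)
        up = rng.random(n_deg) < direction_split
        degs = dict(static_rec)
        for idx, is_up in zip(chosen, up):
            gid = universe[idx]
            lfc = 2.0 if is_up else -2.0
            klass = GeneClass.DEG_UP if is_up else GeneClass.DEG_DOWN
            degs[gid] = DEGRecord(gid, lfc, 0.01, klass)
        clusters = call_clusters(genes, degs, tad_assignment=assignment)
        acc += curve_from_clusters(clusters, min_n, max_n,
                                   max_static_fraction, strict)
    return ProbabilityCurve(np.arange(min_n, max_n + 1), acc / n_iterations,
                            n_iterations, seed)


def ecord_overlap(ecords_a: Sequence[GeneCluster],
                  ecords_b: Sequence[GeneCluster]) -> dict[str, int]:
    """Count spans in each set overlapping (>= 1 bp) any span of the other."""

    def n_overlapping(xs: Sequence[GeneCluster], ys: Sequence[GeneCluster]) -> int:
        return sum(1 for x in xs
                   if any(y.chrom == x.chrom and x.start < y.end and y.start < x.end
                          for y in ys))

    return {"n_a": len(ecords_a), "n_b": len(ecords_b),
            "a_overlapping_b": n_overlapping(ecords_a, ecords_b),
            "b_overlapping_a": n_overlapping(ecords_b, ecords_a)}
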