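"""BGC presence calling, group enrichment, and homology clustering.

Presence of a biosynthetic gene cluster in a metagenomic sample is called by
comparing the observed breadth of coverage with the Lander–Waterman expected
coverage probability

    E = 1 - exp(-N * L_read / L_BGC)

where N is the number of mapped reads, L_read the median read length and
L_BGC the cluster length.  A cluster is called present when the ratio of
actual to expected coverage reaches a threshold (default 0.75).  Presence
frequencies are then compared between treatment groups with Fisher's exact
test and BH correction, and homologous clusters are collapsed by
average-linkage clustering of ORF-family similarity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.spatial.distance

from micropat.stats import ContingencyTable2x2, bh_fdr, fisher_exact_two_sided
from micropat.synthetic import BgcRecord, CoverageObservation

__all__ = [
    "EnrichmentResult",
    "BgcClusterSet",
    "expected_coverage",
    "coverage_ratio",
    "call_presence",
    "bgc_enrichment",
    "cluster_bgcs",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-BGC treatment-group enrichment of presence calls."""

    bgc_id: str
    table: ContingencyTable2x2
    odds_ratio: float
    p: float
    q: float
    enriched_in: str  # "PAT", "control" or "none"


@dataclass(frozen=True)
class BgcClusterSet:
    """Assignment of every BGC to exactly one homology cluster."""

    assignments: dict[str, int]
    linkage: str
    threshold: float

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignments.values()))


def expected_coverage(n_reads: int, read_len: int, bgc_len: int) -> float:
    """Lander–Waterman probability that a base is covered at least once.

    E = 1 - exp(-N * L_read / L_BGC).  Strictly increasing in N and L_read,
    strictly decreasing in L_BGC; bounded in [0, 1).
    """
    if n_reads < 0:
        raise ValueError("n_reads must be non-negative")
    if read_len < 1 or bgc_len < 1:
        raise ValueError("read_len and bgc_len must be >= 1")
    return 1.0 - math.exp(-n_reads * read_len / bgc_len)


def coverage_ratio(obs: CoverageObservation, bgc: BgcRecord) -> float:
    """Ratio of actual coverage breadth to expected coverage.

    Actual coverage is the fraction of BGC bases covered at >= 1x.  The
    ratio is defined as 0 when no reads mapped (expected coverage 0).
    """
    if obs.bgc_id != bgc.bgc_id:
        raise ValueError(f"observation {obs.bgc_id!r} does not match BGC {bgc.bgc_id!r}")
    if obs.covered_bases > bgc.length_bp:
        raise ValueError(f"{obs.bgc_id}: covered_bases exceeds BGC length")
    expected = expected_coverage(obs.n_reads, obs.read_len, bgc.length_bp)
    if expected == 0.0:
        return 0.0
    return (obs.covered_bases / bgc.length_bp) / expected


def call_presence(
    observations: list[CoverageObservation],
    bgcs: list[BgcRecord],
    min_ratio: float = 0.75,
) -> pd.DataFrame:
    """Boolean samples x BGCs presence matrix.

    A BGC is present in a sample iff its coverage ratio is >= min_ratio
    (inclusive).  (sample, BGC) pairs without an observation are treated as
    zero reads, hence absent; the count of such imputed pairs is logged.
    The threshold used is recorded in ``DataFrame.attrs["min_ratio"]``.
    """
    if not 0 < min_ratio < math.inf:
        raise ValueError("min_ratio must be positive and finite")
    by_id = {b.bgc_id: b for b in bgcs}
    unknown = sorted({o.bgc_id for o in observations} - set(by_id))
    if unknown:
        raise ValueError(f"observations reference unknown BGCs: {unknown}")
    samples = sorted({o.sample_id for o in observations})
    bgc_ids = [b.bgc_id for b in bgcs]
    presence = pd.DataFrame(False, index=samples, columns=bgc_ids)
    for o in observations:
        r = coverage_ratio(o, by_id[o.bgc_id])
        if r >= min_ratio:
            presence.loc[o.sample_id, o.bgc_id] = True
    n_missing = len(samples) * len(bgc_ids) - len(observations)
    if n_missing > 0:
        logger.info("imputed %d missing (sample, BGC) pairs as zero coverage", n_missing)
    presence.attrs["min_ratio"] = min_ratio
    return presence


def bgc_enrichment(
    presence: pd.DataFrame,
    meta: pd.DataFrame,
    q_threshold: float = 0.15,
) -> list[EnrichmentResult]:
    """Fisher enrichment of presence calls between the two treatment groups.

    For each BGC a 2x2 table (treatment x presence) is tested two-sided;
    BH correction runs across all tested BGCs, including degenerate
    all-present/all-absent ones (p = 1).  ``enriched_in`` names the group
    with the higher presence frequency when q < q_threshold, else "none".
    """
    meta = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    treatment = meta.loc[presence.index, "treatment"]
    levels = sorted(treatment.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two treatment levels, got {levels}")
    pat_mask = (treatment == "PAT").to_numpy()
    if not pat_mask.any() or pat_mask.all():
        raise ValueError("need samples in both treatment groups")

    tables, pvals = [], []
    for bgc_id in presence.columns:
        present = presence[bgc_id].to_numpy(dtype=bool)
        a = int((present & pat_mask).sum())        # PAT, present
        b = int((~present & pat_mask).sum())       # PAT, absent
        c = int((present & ~pat_mask).sum())       # control, present
        d = int((~present & ~pat_mask).sum())      # control, absent
        table = ContingencyTable2x2(a, b, c, d)
        tables.append(table)
        pvals.append(fisher_exact_two_sided(table))
    qvals = bh_fdr(np.array(pvals))

    results = []
    n_pat, n_ctl = int(pat_mask.sum()), int((~pat_mask).sum())
    for bgc_id, table, p, q in zip(presence.columns, tables, pvals, qvals):
        direction = "none"
        if q < q_threshold:
            freq_pat = table.a / n_pat
            freq_ctl = table.c / n_ctl
            if freq_pat > freq_ctl:
                direction = "PAT"
            elif freq_ctl > freq_pat:
                direction = "control"
        results.append(
            EnrichmentResult(
                bgc_id=str(bgc_id),
                table=table,
                odds_ratio=table.odds_ratio,
                p=float(p),
                q=float(q),
                enriched_in=direction,
            )
        )
    return results


def orf_jaccard_similarity(bgcs: list[BgcRecord]) -> pd.DataFrame:
    """Pairwise Jaccard index of ORF-family sets, as a symmetric DataFrame."""
    ids = [b.bgc_id for b in bgcs]
    sets = [b.orf_families for b in bgcs]
    n = len(bgcs)
    sim = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            union = len(sets[i] | sets[j])
            sim[i, j] = sim[j, i] = (
                len(sets[i] & sets[j]) / union if union else 1.0
            )
    return pd.DataFrame(sim, index=ids, columns=ids)


def cluster_bgcs(
    bgcs: list[BgcRecord],
    similarity: pd.DataFrame | None = None,
    threshold: float = 0.5,
    linkage: str = "average",
) -> BgcClusterSet:
    """Collapse homologous BGCs by average-linkage agglomeration.

    Similarity defaults to the Jaccard index of ORF-family sets; a
    user-supplied matrix (e.g. amino-acid identity) may be passed instead.
    Clusters are merged while the linkage similarity is >= threshold, i.e.
    the dendrogram is cut at distance 1 - threshold.  BGCs are processed in
    lexicographic id order for a deterministic tie-break.
    """
    if linkage != "average":
        raise ValueError("only average linkage is supported")
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    order = sorted(range(len(bgcs)), key=lambda i: bgcs[i].bgc_id)
    bgcs = [bgcs[i] for i in order]
    ids = [b.bgc_id for b in bgcs]
    if similarity is None:
        similarity = orf_jaccard_similarity(bgcs)
    else:
        sim = np.asarray(similarity, dtype=float)
        if sim.shape != (len(bgcs), len(bgcs)) or not np.allclose(sim, sim.T):
            raise ValueError("similarity must be a square symmetric matrix")
        similarity = pd.DataFrame(sim, index=similarity.index, columns=similarity.columns)
        similarity = similarity.loc[ids, ids]
    if len(bgcs) == 1:
        return BgcClusterSet({ids[0]: 1}, linkage, threshold)
    dist = 1.0 - similarity.to_numpy()
    np.fill_diagonal(dist, 0.0)
    condensed = scipy.spatial.distance.squareform(dist, checks=False)
    z = scipy.cluster.hierarchy.linkage(condensed, method=linkage)
    labels = scipy.cluster.hierarchy.fcluster(z, t=1.0 - threshold, criterion="distance")
    return BgcClusterSet(dict(zip(ids, (int(x) for x in labels))), linkage, threshold)
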