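"""Five-class classification of gene-expression maturation under a perturbation.

"Maturation" of a gene is a significant change in its expression between two
developmental timepoints (e.g. postnatal days 12 and 42).  Testing each gene
separately in the control and the perturbed (PAT) arm yields five mutually
exclusive classes:

* ``I_only`` — matures in the control arm only,
* ``III``   — matures in both arms, same direction (perturbation-resistant),
* ``IV``    — matures in both arms, opposite directions (perturbation-altered),
* ``V``     — matures only under the perturbation (dysmaturation),
* ``NC``    — no significant change in either arm.

The marginal classes of the original scheme — I, "maturing in control", and
II, "maturing under the perturbation" — overlap III–V; they are reported as
``marginal_I`` / ``marginal_II`` flags so either reading is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from micropat.stats import (
    ContingencyTable2x2,
    bh_fdr,
    fisher_exact_two_sided,
    median_ratio_normalize,
    welch_log_test,
)

__all__ = [
    "ArmStats",
    "MaturationCall",
    "GeneSetCollection",
    "maturation_test",
    "classify_maturation",
    "summarize_classes",
    "pathway_enrichment",
]

PRIMARY_CLASSES = ("I_only", "III", "IV", "V", "NC")


@dataclass(frozen=True)
class ArmStats:
    """Two-timepoint test result for one gene in one arm."""

    gene: str
    arm: str  # "control" or "PAT"
    log2fc: float  # t1 vs t0
    p: float
    q: float
    direction: str  # "up", "down" or "none"; none iff q >= alpha


@dataclass(frozen=True)
class MaturationCall:
    gene: str
    control: ArmStats
    pat: ArmStats
    primary_class: str
    marginal_I: bool  # matures in control (traditional class I)
    marginal_II: bool  # matures under the perturbation (traditional class II)


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets over a fixed gene universe (GMT-style)."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            stray = members - self.universe
            if stray:
                raise ValueError(
                    f"pathway {name!r} contains genes outside the universe: "
                    f"{sorted(stray)[:5]}"
                )


def maturation_test(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    arm: str,
    t0: int,
    t1: int,
    alpha: float = 0.05,
) -> dict[str, ArmStats]:
    """Per-gene two-timepoint test within one arm.

    The arm's samples (both timepoints) are median-ratio normalized together,
    log2(x+1)-transformed, and each gene tested t0 vs t1 with Welch's t-test;
    BH correction runs across genes within the arm.  Direction follows the
    sign of the log2 fold-change when q < alpha.
    """
    if t0 == t1:
        raise ValueError("t0 and t1 must differ")
    meta = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    arm_meta = meta[meta["treatment"] == arm]
    s0 = arm_meta.index[arm_meta["day"] == t0]
    s1 = arm_meta.index[arm_meta["day"] == t1]
    for label, s in ((t0, s0), (t1, s1)):
        if len(s) < 2:
            raise ValueError(f"arm {arm!r}, day {label}: need >= 2 samples, got {len(s)}")
    samples = list(s0) + list(s1)
    counts = expr[samples].to_numpy(dtype=float)
    try:
        _, normed = median_ratio_normalize(counts)
    except ValueError:
        _, normed = median_ratio_normalize(counts + 1.0)
    log_expr = np.log2(normed + 1.0)
    n0 = len(s0)

    genes = list(expr.index)
    directions, pvals, lfcs = [], [], []
    for i in range(len(genes)):
        g0, g1 = log_expr[i, :n0], log_expr[i, n0:]
        direction, p = welch_log_test(g0, g1)
        directions.append(direction)
        pvals.append(p)
        lfcs.append(float(g1.mean() - g0.mean()))
    qvals = bh_fdr(np.array(pvals))

    out = {}
    for gene, direction, p, q, lfc in zip(genes, directions, pvals, qvals, lfcs):
        if q >= alpha:
            direction = "none"
        out[gene] = ArmStats(
            gene=gene, arm=arm, log2fc=lfc, p=float(p), q=float(q), direction=direction
        )
    return out


def classify_maturation(control: ArmStats, pat: ArmStats) -> MaturationCall:
    """Assign a gene to one of the five exclusive maturation classes."""
    if control.gene != pat.gene:
        raise ValueError(f"mismatched genes: {control.gene!r} vs {pat.gene!r}")
    ctl_sig = control.direction != "none"
    pat_sig = pat.direction != "none"
    if ctl_sig and pat_sig:
        primary = "III" if control.direction == pat.direction else "IV"
    elif ctl_sig:
        primary = "I_only"
    elif pat_sig:
        primary = "V"
    else:
        primary = "NC"
    return MaturationCall(
        gene=control.gene,
        control=control,
        pat=pat,
        primary_class=primary,
        marginal_I=ctl_sig,
        marginal_II=pat_sig,
    )


def summarize_classes(calls: list[MaturationCall]) -> pd.Series:
    """Counts per primary class, marginal totals, and up/down splits."""
    if not calls:
        raise ValueError("no maturation calls to summarize")
    counts = {cls: 0 for cls in PRIMARY_CLASSES}
    marginal_i = marginal_ii = 0
    up_ctl = down_ctl = up_pat = down_pat = 0
    for call in calls:
        counts[call.primary_class] += 1
        marginal_i += call.marginal_I
        marginal_ii += call.marginal_II
        up_ctl += call.control.direction == "up"
        down_ctl += call.control.direction == "down"
        up_pat += call.pat.direction == "up"
        down_pat += call.pat.direction == "down"
    counts.update(
        marginal_I=marginal_i,
        marginal_II=marginal_ii,
        control_up=up_ctl,
        control_down=down_ctl,
        PAT_up=up_pat,
        PAT_down=down_pat,
        total=len(calls),
    )
    return pd.Series(counts)


def pathway_enrichment(
    class_genes: set[str],
    sets: GeneSetCollection,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fisher over-representation of a gene class in each pathway.

    Per pathway, a 2x2 table of (in class) x (in pathway) over the universe
    is tested two-sided; BH runs across pathways.  Returns a DataFrame
    indexed by pathway with columns overlap, size, p, q, significant.
    """
    stray = set(class_genes) - sets.universe
    if stray:
        raise ValueError(f"class genes outside the universe: {sorted(stray)[:5]}")
    n_universe = len(sets.universe)
    n_class = len(class_genes)
    rows = []
    for name in sorted(sets.sets):
        members = sets.sets[name]
        overlap = len(class_genes & members)
        a = overlap
        b = n_class - overlap
        c = len(members) - overlap
        d = n_universe - n_class - c
        p = fisher_exact_two_sided(ContingencyTable2x2(a, b, c, d))
        rows.append({"pathway": name, "overlap": overlap, "size": len(members), "p": p})
    result = pd.DataFrame(rows).set_index("pathway")
    result["q"] = bh_fdr(result["p"].to_numpy())
    result["significant"] = result["q"] < alpha
    return result
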