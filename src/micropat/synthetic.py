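"""Synthetic-data generators with planted ground truth.

Each generator emulates the statistical structure of one input of the real
study design — a 2 (sex) x 2 (treatment) crossing of mouse pups sampled at
several postnatal days — and returns both the data and a
:class:`PlantedTruth` sidecar recording exactly what was planted, so recovery
tests never have to re-derive the truth.

Generators are bit-reproducible given (parameters, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MATURATION_CLASSES",
    "BgcRecord",
    "CoverageObservation",
    "PlantedTruth",
    "generate_metadata",
    "generate_taxa_counts",
    "generate_expression",
    "generate_bgc_reference",
    "generate_bgc_coverage_experiment",
    "simulate_read_coverage",
    "generate_paired_taxa_gene",
]

#: Planted maturation classes.  "I_only": shifts in the control arm only;
#: "III": both arms, same sign; "IV": both arms, opposite signs; "V":
#: perturbed (PAT) arm only; "NC": static.  The study's marginal class II
#: ("maturing under PAT") is the union III+IV+V and is not planted separately.
MATURATION_CLASSES = ("I_only", "III", "IV", "V", "NC")

_PRODUCT_CLASSES = ("siderophore", "aryl polyene", "NRPS", "polysaccharide")
_TAXA = ("Enterobacteriaceae", "Enterococcaceae", "Lachnospiraceae", "Bacteroidaceae")


@dataclass(frozen=True)
class BgcRecord:
    """Reference entry for one biosynthetic gene cluster."""

    bgc_id: str
    length_bp: int
    orf_families: frozenset[str]
    taxon: str = "unknown"
    characterized: bool = False
    product_class: str = "unknown"

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise ValueError(f"{self.bgc_id}: length_bp must be >= 1")


@dataclass(frozen=True)
class CoverageObservation:
    """Read coverage of one BGC in one sample: read count and breadth."""

    sample_id: str
    bgc_id: str
    n_reads: int
    read_len: int
    covered_bases: int

    def __post_init__(self) -> None:
        if self.n_reads < 0 or self.covered_bases < 0:
            raise ValueError("counts must be non-negative")
        if self.n_reads == 0 and self.covered_bases != 0:
            raise ValueError("zero reads cannot cover any base")


@dataclass
class PlantedTruth:
    """Ground truth written next to every generated dataset.

    Only the fields relevant to the generator that produced it are filled.
    """

    seed: int
    params: dict = field(default_factory=dict)
    #: taxon -> signed log2 fold-change of expected relative abundance (PAT/control)
    taxa_log2fc: dict[str, float] = field(default_factory=dict)
    #: gene -> planted class (one of MATURATION_CLASSES)
    gene_class: dict[str, str] = field(default_factory=dict)
    #: gene -> {"control": log2fc, "PAT": log2fc} planted t1/t0 shifts
    gene_log2fc: dict[str, dict[str, float]] = field(default_factory=dict)
    #: sparse taxon x gene coefficient matrix (None unless paired generator)
    coefficients: pd.DataFrame | None = None

    def true_edges(self) -> set[tuple[str, str]]:
        if self.coefficients is None:
            return set()
        stacked = self.coefficients.stack()
        return {(t, g) for (t, g), v in stacked.items() if v != 0}

    def to_json(self) -> str:
        doc = {
            "seed": self.seed,
            "params": self.params,
            "taxa_log2fc": self.taxa_log2fc,
            "gene_class": self.gene_class,
            "gene_log2fc": self.gene_log2fc,
            "coefficients": None
            if self.coefficients is None
            else {
                "index": list(self.coefficients.index),
                "columns": list(self.coefficients.columns),
                "values": self.coefficients.to_numpy().tolist(),
            },
        }
        return json.dumps(doc, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PlantedTruth":
        doc = json.loads(text)
        coef = doc.get("coefficients")
        if coef is not None:
            coef = pd.DataFrame(
                np.asarray(coef["values"], dtype=float),
                index=coef["index"],
                columns=coef["columns"],
            )
        return cls(
            seed=doc["seed"],
            params=doc.get("params", {}),
            taxa_log2fc=doc.get("taxa_log2fc", {}),
            gene_class=doc.get("gene_class", {}),
            gene_log2fc=doc.get("gene_log2fc", {}),
            coefficients=coef,
        )


def generate_metadata(
    n_mice_per_cell: int,
    timepoints: Sequence[int],
    seed: int = 0,
) -> pd.DataFrame:
    """Full 2(sex) x 2(treatment) crossing, one sample per mouse per timepoint.

    Returns a DataFrame with columns sample_id, mouse_id, sex, treatment, day.
    """
    if n_mice_per_cell < 1:
        raise ValueError("n_mice_per_cell must be >= 1")
    timepoints = list(timepoints)
    if not timepoints:
        raise ValueError("timepoints must be non-empty")
    rows = []
    mouse_no = 0
    for treatment in ("control", "PAT"):
        for sex in ("M", "F"):
            for _ in range(n_mice_per_cell):
                mouse_no += 1
                mouse_id = f"m{mouse_no:03d}"
                for day in timepoints:
                    rows.append(
                        {
                            "sample_id": f"{mouse_id}.P{day}",
                            "mouse_id": mouse_id,
                            "sex": sex,
                            "treatment": treatment,
                            "day": int(day),
                        }
                    )
    return pd.DataFrame(rows)


def _dirichlet_multinomial(
    rng: np.random.Generator,
    props: np.ndarray,
    depth: int,
    overdispersion: float,
) -> np.ndarray:
    """One sample of depth reads around the given expected proportions."""
    if overdispersion > 0:
        alpha = props / overdispersion
        props = rng.dirichlet(alpha)
    return rng.multinomial(depth, props)


def generate_taxa_counts(
    meta: pd.DataFrame,
    n_taxa: int = 200,
    n_up: int = 4,
    n_down: int = 4,
    log2_effect: float = 2.0,
    depth: int = 50_000,
    overdispersion: float = 0.005,
    seed: int = 0,
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Compositional taxa counts with planted over/under-represented taxa.

    Counts are Dirichlet-multinomial around log-normal baseline proportions;
    in PAT samples the expected relative abundance of the ``n_up`` planted
    taxa is multiplied by ``2**log2_effect`` and that of the ``n_down`` taxa
    divided by it, then renormalized.  Row sums equal ``depth`` exactly.
    Returns (samples x taxa counts, truth).
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if log2_effect < 0:
        raise ValueError("log2_effect must be non-negative")
    if n_up + n_down > n_taxa:
        raise ValueError("n_up + n_down must not exceed n_taxa")
    rng = np.random.default_rng(seed)
    taxa = [f"taxon{i:03d}" for i in range(n_taxa)]
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_taxa)
    base /= base.sum()
    planted = rng.choice(n_taxa, size=n_up + n_down, replace=False)
    up_idx, down_idx = planted[:n_up], planted[n_up:]

    effect = 2.0**log2_effect
    pat = base.copy()
    pat[up_idx] *= effect
    pat[down_idx] /= effect
    pat /= pat.sum()

    counts = np.empty((len(meta), n_taxa), dtype=np.int64)
    for i, treatment in enumerate(meta["treatment"]):
        props = pat if treatment == "PAT" else base
        counts[i] = _dirichlet_multinomial(rng, props, depth, overdispersion)
    table = pd.DataFrame(counts, index=list(meta["sample_id"]), columns=taxa)

    truth = PlantedTruth(
        seed=seed,
        params={
            "n_taxa": n_taxa,
            "n_up": n_up,
            "n_down": n_down,
            "log2_effect": log2_effect,
            "depth": depth,
            "overdispersion": overdispersion,
        },
        taxa_log2fc={
            **{taxa[i]: float(np.log2(pat[i] / base[i])) for i in up_idx},
            **{taxa[i]: float(np.log2(pat[i] / base[i])) for i in down_idx},
        },
    )
    return table, truth


def generate_expression(
    meta: pd.DataFrame,
    n_genes: int = 547,
    class_counts: dict[str, int] | None = None,
    log2_effect: float = 2.0,
    dispersion: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, PlantedTruth]:
    """Overdispersed expression counts with planted maturation classes.

    Negative-binomial counts around log-normal baseline means.  The metadata
    must contain exactly two timepoints; each planted gene's mean shifts
    between them by +/- ``log2_effect`` (sign drawn per gene per arm) in the
    arm(s) its class prescribes: I_only in control only, III in both arms
    with the same sign, IV in both arms with opposite signs, V in PAT only.
    Remaining genes are static.  Returns (genes x samples counts, truth).
    """
    if class_counts is None:
        class_counts = {"I_only": 30, "III": 30, "IV": 20, "V": 20}
    unknown = set(class_counts) - set(MATURATION_CLASSES)
    if unknown:
        raise ValueError(f"unknown maturation classes: {sorted(unknown)}")
    n_planted = sum(class_counts.values())
    if n_planted > n_genes:
        raise ValueError("sum of class_counts exceeds n_genes")
    days = sorted(meta["day"].unique())
    if len(days) != 2:
        raise ValueError("metadata must contain exactly two timepoints")
    t0, t1 = days

    rng = np.random.default_rng(seed)
    genes = [f"gene{i:04d}" for i in range(n_genes)]
    base_mean = rng.lognormal(mean=5.0, sigma=1.0, size=n_genes)

    gene_class = {g: "NC" for g in genes}
    gene_log2fc = {g: {"control": 0.0, "PAT": 0.0} for g in genes}
    order = rng.permutation(n_genes)
    cursor = 0
    for cls in ("I_only", "III", "IV", "V"):
        for _ in range(class_counts.get(cls, 0)):
            g = genes[order[cursor]]
            cursor += 1
            gene_class[g] = cls
            sign = float(rng.choice([-1.0, 1.0]))
            if cls == "I_only":
                gene_log2fc[g] = {"control": sign * log2_effect, "PAT": 0.0}
            elif cls == "III":
                gene_log2fc[g] = {"control": sign * log2_effect, "PAT": sign * log2_effect}
            elif cls == "IV":
                gene_log2fc[g] = {"control": sign * log2_effect, "PAT": -sign * log2_effect}
            else:  # V
                gene_log2fc[g] = {"control": 0.0, "PAT": sign * log2_effect}

    lfc = np.array(
        [[gene_log2fc[g]["control"], gene_log2fc[g]["PAT"]] for g in genes]
    )
    counts = np.empty((n_genes, len(meta)), dtype=np.int64)
    for j, (_, row) in enumerate(meta.iterrows()):
        arm = 1 if row["treatment"] == "PAT" else 0
        mu = base_mean * np.where(row["day"] == t1, 2.0 ** lfc[:, arm], 1.0)
        if dispersion > 0:
            # NB parametrized by mean mu and dispersion a: var = mu + a*mu^2
            n_param = 1.0 / dispersion
            p_param = n_param / (n_param + mu)
            counts[:, j] = rng.negative_binomial(n_param, p_param)
        else:
            counts[:, j] = rng.poisson(mu)
    table = pd.DataFrame(counts, index=genes, columns=list(meta["sample_id"]))

    truth = PlantedTruth(
        seed=seed,
        params={
            "n_genes": n_genes,
            "class_counts": dict(class_counts),
            "log2_effect": log2_effect,
            "dispersion": dispersion,
            "t0": int(t0),
            "t1": int(t1),
        },
        gene_class=gene_class,
        gene_log2fc=gene_log2fc,
    )
    return table, truth


def generate_bgc_reference(
    n_bgcs: int = 228,
    length_range: tuple[int, int] = (5_000, 50_000),
    n_orf_families: int = 9,
    n_homology_groups: int = 3,
    seed: int = 0,
) -> list[BgcRecord]:
    """Toy BGC reference with controlled homology structure.

    BGCs in the same homology group share a core of ``n_orf_families`` ORF
    families plus one member-specific family, so within-group Jaccard is
    ``n / (n + 2) >= 0.8`` for the default core size; distinct groups draw
    from disjoint family pools, so between-group Jaccard is 0.
    """
    if length_range[0] < 1 or length_range[1] < length_range[0]:
        raise ValueError("invalid length_range")
    if not (1 <= n_homology_groups <= n_bgcs):
        raise ValueError("need n_bgcs >= n_homology_groups >= 1")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_bgcs):
        group = i % n_homology_groups
        core = frozenset(f"g{group}.fam{k}" for k in range(n_orf_families))
        families = core | {f"g{group}.private{i}"}
        records.append(
            BgcRecord(
                bgc_id=f"BGC{i:04d}",
                length_bp=int(rng.integers(length_range[0], length_range[1] + 1)),
                orf_families=families,
                taxon=_TAXA[group % len(_TAXA)],
                characterized=bool(rng.random() < 0.2),
                product_class=_PRODUCT_CLASSES[group % len(_PRODUCT_CLASSES)],
            )
        )
    return records


def simulate_read_coverage(
    bgc: BgcRecord,
    n_reads: int,
    read_len: int,
    seed: int = 0,
    sample_id: str = "sim",
) -> CoverageObservation:
    """Uniform-start shotgun coverage of one BGC.

    Read start positions are uniform on [0, L-1]; reads are clipped at the
    3' end rather than wrapped.  A read at least as long as the BGC covers
    it entirely wherever it aligns.  covered_bases is the size of the union
    of the read intervals.
    """
    if read_len < 1:
        raise ValueError("read_len must be >= 1")
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    L = bgc.length_bp
    if n_reads == 0:
        return CoverageObservation(sample_id, bgc.bgc_id, 0, read_len, 0)
    if read_len >= L:
        return CoverageObservation(sample_id, bgc.bgc_id, n_reads, read_len, L)
    rng = np.random.default_rng(seed)
    starts = np.sort(rng.integers(0, L, size=n_reads))
    ends = np.minimum(starts + read_len, L)
    covered = 0
    cur_start, cur_end = int(starts[0]), int(ends[0])
    for s, e in zip(starts[1:], ends[1:]):
        if s <= cur_end:
            cur_end = max(cur_end, int(e))
        else:
            covered += cur_end - cur_start
            cur_start, cur_end = int(s), int(e)
    covered += cur_end - cur_start
    return CoverageObservation(sample_id, bgc.bgc_id, n_reads, read_len, covered)


def generate_bgc_coverage_experiment(
    meta: pd.DataFrame,
    bgcs: Sequence[BgcRecord],
    n_enriched: int = 20,
    p_background: float = 0.5,
    p_enriched_pat: float = 0.9,
    p_enriched_control: float = 0.1,
    read_len: int = 100,
    target_fold_coverage: float = 3.0,
    seed: int = 0,
) -> tuple[list[CoverageObservation], dict[str, bool]]:
    """Coverage observations with a planted set of PAT-enriched BGCs.

    Each (sample, BGC) pair is first assigned carriage: planted BGCs are
    carried with probability ``p_enriched_pat`` in PAT samples and
    ``p_enriched_control`` in controls; background BGCs with
    ``p_background`` in both groups.  Carried BGCs receive enough uniform
    reads for ~``target_fold_coverage``-fold depth (coverage ratio near 1);
    uncarried BGCs receive none.  Returns the observation list and a map
    bgc_id -> planted-enriched flag.
    """
    if n_enriched > len(bgcs):
        raise ValueError("n_enriched exceeds the number of BGCs")
    rng = np.random.default_rng(seed)
    enriched_ids = {
        bgcs[i].bgc_id for i in rng.choice(len(bgcs), size=n_enriched, replace=False)
    }
    observations = []
    for _, row in meta.iterrows():
        is_pat = row["treatment"] == "PAT"
        for b in bgcs:
            if b.bgc_id in enriched_ids:
                p_carry = p_enriched_pat if is_pat else p_enriched_control
            else:
                p_carry = p_background
            if rng.random() < p_carry:
                n_reads = max(1, int(target_fold_coverage * b.length_bp / read_len))
                obs = simulate_read_coverage(
                    b, n_reads, read_len, seed=int(rng.integers(2**31)),
                    sample_id=row["sample_id"],
                )
            else:
                obs = CoverageObservation(row["sample_id"], b.bgc_id, 0, read_len, 0)
            observations.append(obs)
    truth = {b.bgc_id: b.bgc_id in enriched_ids for b in bgcs}
    return observations, truth


def generate_paired_taxa_gene(
    meta: pd.DataFrame,
    n_taxa: int = 15,
    n_genes: int = 43,
    n_true_edges: int = 25,
    coefficient_scale: float = 1.0,
    noise_sd: float = 0.5,
    stratum_offset_sd: float = 0.5,
    depth: int = 50_000,
    gene_scale: float = 200.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, PlantedTruth]:
    """Paired taxa and gene tables with planted sparse linear associations.

    Latent clr-scale taxa signals (rows centered, so the clr of the exported
    composition recovers them exactly up to multinomial noise) drive gene
    responses through a sparse taxon x gene coefficient matrix with
    ``n_true_edges`` nonzeros of magnitude ``coefficient_scale`` and random
    signs, plus sex x treatment stratum offsets and Gaussian noise.  Taxa are
    exported as multinomial counts of the softmax composition; genes as
    exponentiated counts.  Returns (taxa samples x taxa, genes x samples,
    truth with the coefficient matrix).
    """
    if n_true_edges > n_taxa * n_genes:
        raise ValueError("n_true_edges exceeds the number of possible edges")
    rng = np.random.default_rng(seed)
    n = len(meta)
    taxa = [f"taxon{i:02d}" for i in range(n_taxa)]
    genes = [f"gene{i:02d}" for i in range(n_genes)]

    z = rng.normal(size=(n, n_taxa))
    z -= z.mean(axis=1, keepdims=True)  # clr-scale: rows sum to zero

    coef = np.zeros((n_taxa, n_genes))
    if n_true_edges > 0:
        flat = rng.choice(n_taxa * n_genes, size=n_true_edges, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_true_edges)
        coef.flat[flat] = signs * coefficient_scale

    strata = meta["sex"].astype(str) + ":" + meta["treatment"].astype(str)
    g = z @ coef
    for s in sorted(strata.unique()):
        mask = (strata == s).to_numpy()
        g[mask] += rng.normal(scale=stratum_offset_sd, size=n_genes)[None, :]
    if noise_sd > 0:
        g += rng.normal(scale=noise_sd, size=g.shape)

    # export: taxa as multinomial counts of softmax(z), genes as exp counts
    taxa_counts = np.empty((n, n_taxa), dtype=np.int64)
    for i in range(n):
        props = np.exp(z[i])
        props /= props.sum()
        taxa_counts[i] = rng.multinomial(depth, props)
    gene_counts = np.rint(np.exp(g) * gene_scale).astype(np.int64).T

    taxa_table = pd.DataFrame(taxa_counts, index=list(meta["sample_id"]), columns=taxa)
    expr_table = pd.DataFrame(gene_counts, index=genes, columns=list(meta["sample_id"]))
    truth = PlantedTruth(
        seed=seed,
        params={
            "n_taxa": n_taxa,
            "n_genes": n_genes,
            "n_true_edges": n_true_edges,
            "coefficient_scale": coefficient_scale,
            "noise_sd": noise_sd,
            "stratum_offset_sd": stratum_offset_sd,
            "depth": depth,
            "gene_scale": gene_scale,
        },
        coefficients=pd.DataFrame(coef, index=taxa, columns=genes),
    )
    return taxa_table, expr_table, truth
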