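"""Synthetic datasets with planted ground truth for every pipeline stage.

Generates gene annotations with disjoint promoter windows, peak sets
that exactly realize planted per-gene chromatin states in two
conditions, two-condition expression tables with a planted repression
effect in Group I, cohort matrices with a planted gene-set depression
in TN-like samples, term ontologies with a planted enriched term, and
qPCR/ChIP-qPCR Ct tables with planted fold changes.

All generators are pure functions of (spec, seed): the same seed
yields byte-identical output files. The chromatin channel is noiseless
by default (replaying the classifier recovers the planted groups
exactly); an optional peak-dropout rate simulates mark miscalls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from bivtrans.annotation_io import (
    MARK_K4,
    MARK_K27,
    GeneAnnotation,
    GenomicInterval,
    Peak,
    promoter_window,
    write_bed,
)
from bivtrans.enrichment import TermAnnotation, write_gmt
from bivtrans.state_classifier import ChromatinState, TransitionGroup

# planted condition-A state per transition group
_GROUP_STATE_A = {
    TransitionGroup.I: ChromatinState.K4_ONLY,
    TransitionGroup.II: ChromatinState.K27_ONLY,
    TransitionGroup.III: ChromatinState.UNMARKED,
    TransitionGroup.IV: ChromatinState.BIVALENT,
}

_STATE_MARKS = {
    ChromatinState.K4_ONLY: (True, False),
    ChromatinState.K27_ONLY: (False, True),
    ChromatinState.BIVALENT: (True, True),
    ChromatinState.UNMARKED: (False, False),
}


def default_group_proportions() -> dict[TransitionGroup, float]:
    """Default planted group proportions over all genes.

    30% of genes are bivalent in condition B, split so that Group I
    accounts for 47% of them (the observed predominant route); the
    remaining 70% of genes stay non-bivalent in B.
    """
    bivalent_b = 0.30
    split = {
        TransitionGroup.I: 0.47,
        TransitionGroup.II: 0.18,
        TransitionGroup.III: 0.20,
        TransitionGroup.IV: 0.15,
    }
    out = {g: bivalent_b * f for g, f in split.items()}
    out[TransitionGroup.NONE] = 1.0 - bivalent_b
    return out


@dataclass
class SyntheticSpec:
    """Parameters of a planted synthetic dataset."""

    n_genes: int = 2000
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 30_000_000, "chr2": 30_000_000}
    )
    group_proportions: dict[TransitionGroup, float] = field(
        default_factory=default_group_proportions
    )
    # overall fraction of genes bivalent in condition A; with the
    # default proportions this plants a ~2.7-fold bivalency increase
    bivalent_fraction_a: float = 0.30 * 0.15 + 0.066
    repression_prob_group_I: float = 0.694
    effect_scale: float = 2.0
    expression_noise_sd: float = 0.4
    n_tn: int = 50
    n_non_tn: int = 50
    cohort_delta: float = 1.0
    cohort_noise_sd: float = 1.0
    promoter_upstream: int = 2000
    promoter_downstream: int = 2000
    peak_dropout: float = 0.0
    n_decoy_peaks: int = 0
    condition_a: str = "vector"
    condition_b: str = "twist"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        total = sum(self.group_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"group proportions must sum to 1, got {total}")
        for name in (
            "bivalent_fraction_a",
            "repression_prob_group_I",
            "peak_dropout",
        ):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {value}")


@dataclass
class SyntheticDataset:
    spec: SyntheticSpec
    annotation: list[GeneAnnotation]
    peaks: dict[tuple[str, str], list[Peak]]  # (mark, condition) -> peaks
    truth_groups: dict[str, TransitionGroup]
    truth_states: dict[str, tuple[ChromatinState, ChromatinState]]
    expression: pd.DataFrame
    cohort_matrix: pd.DataFrame
    cohort_metadata: pd.DataFrame
    ontology: list[TermAnnotation]
    rt_ct_table: pd.DataFrame
    rt_truth: pd.DataFrame
    chip_table: pd.DataFrame


def generate_annotation(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> list[GeneAnnotation]:
    """Lay out genes with pairwise-disjoint promoter windows.

    Genes are placed sequentially with guard gaps on alternating
    random strands; raises if the chromosomes cannot accommodate
    ``n_genes`` disjoint windows.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    window = spec.promoter_upstream + spec.promoter_downstream
    max_body = 8_000
    # slot guarantees adjacent promoter windows cannot touch on either strand
    slot = max_body + 2 * window + 2_000
    lead = window + 1_000  # keeps windows clear of the chromosome origin
    capacity = sum(
        max(0, (size - lead)) // slot for size in spec.chrom_sizes.values()
    )
    if capacity < spec.n_genes:
        raise ValueError(
            f"chromosomes fit only {capacity} disjoint promoters, "
            f"need {spec.n_genes}"
        )
    genes: list[GeneAnnotation] = []
    chroms = list(spec.chrom_sizes.items())
    chrom_idx = 0
    cursor = lead
    width = len(str(spec.n_genes))
    for i in range(spec.n_genes):
        while cursor + slot > chroms[chrom_idx][1]:
            chrom_idx += 1
            cursor = lead
        chrom = chroms[chrom_idx][0]
        strand = "+" if rng.random() < 0.5 else "-"
        body_len = int(rng.integers(2_000, max_body))
        genes.append(
            GeneAnnotation(
                f"G{str(i).zfill(width)}",
                f"SYN{str(i).zfill(width)}",
                GenomicInterval(chrom, cursor, cursor + body_len, strand),
            )
        )
        cursor += slot
    return genes


def _place_peak(
    promoter: GenomicInterval, rng: np.random.Generator
) -> GenomicInterval:
    """A peak interval strictly inside the promoter window."""
    width = int(rng.integers(200, max(201, len(promoter) // 2)))
    width = min(width, len(promoter) - 2)
    offset = int(rng.integers(0, len(promoter) - width))
    start = promoter.start + offset
    return GenomicInterval(promoter.chrom, start, start + width)


def generate_condition_peaks(
    annotation: Sequence[GeneAnnotation],
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
) -> tuple[
    dict[tuple[str, str], list[Peak]],
    dict[str, TransitionGroup],
    dict[str, tuple[ChromatinState, ChromatinState]],
]:
    """Plant transition groups and emit realizing peak sets.

    Each gene draws a group from ``spec.group_proportions``; the
    condition-A state follows the group definition (NONE genes draw a
    non-transitioning state, bivalent in A with the residual
    probability needed to hit ``spec.bivalent_fraction_a`` overall).
    Peaks are placed inside the promoter window for exactly the marks
    each planted state requires.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed + 1)
    groups = list(spec.group_proportions.keys())
    probs = np.array([spec.group_proportions[g] for g in groups])
    draws = rng.choice(len(groups), size=len(annotation), p=probs / probs.sum())

    p_none = spec.group_proportions.get(TransitionGroup.NONE, 0.0)
    p_iv = spec.group_proportions.get(TransitionGroup.IV, 0.0)
    # probability that a NONE gene is bivalent in A, chosen so the
    # overall bivalent-in-A fraction matches the spec
    p_biv_a_none = (
        max(0.0, min(1.0, (spec.bivalent_fraction_a - p_iv) / p_none))
        if p_none > 0
        else 0.0
    )

    peaks: dict[tuple[str, str], list[Peak]] = {
        (mark, cond): []
        for mark in (MARK_K4, MARK_K27)
        for cond in (spec.condition_a, spec.condition_b)
    }
    truth_groups: dict[str, TransitionGroup] = {}
    truth_states: dict[str, tuple[ChromatinState, ChromatinState]] = {}

    non_bivalent = [
        ChromatinState.K4_ONLY,
        ChromatinState.K27_ONLY,
        ChromatinState.UNMARKED,
    ]
    for gene, gidx in zip(annotation, draws):
        group = groups[gidx]
        if group is TransitionGroup.NONE:
            if rng.random() < p_biv_a_none:
                state_a = ChromatinState.BIVALENT
                # must lose bivalency in B
                state_b = non_bivalent[int(rng.integers(0, 3))]
            else:
                state_a = non_bivalent[int(rng.integers(0, 3))]
                state_b = non_bivalent[int(rng.integers(0, 3))]
        else:
            state_a = _GROUP_STATE_A[group]
            state_b = ChromatinState.BIVALENT
        truth_groups[gene.gene_id] = group
        truth_states[gene.gene_id] = (state_a, state_b)

        promoter = promoter_window(
            gene, spec.promoter_upstream, spec.promoter_downstream
        )
        for cond, state in (
            (spec.condition_a, state_a),
            (spec.condition_b, state_b),
        ):
            k4, k27 = _STATE_MARKS[state]
            for mark, present in ((MARK_K4, k4), (MARK_K27, k27)):
                if not present:
                    continue
                if spec.peak_dropout > 0 and rng.random() < spec.peak_dropout:
                    continue
                peaks[(mark, cond)].append(
                    Peak(_place_peak(promoter, rng), mark=mark, condition=cond)
                )

    if spec.n_decoy_peaks > 0:
        chroms = list(spec.chrom_sizes.items())
        promoters = [
            promoter_window(g, spec.promoter_upstream, spec.promoter_downstream)
            for g in annotation
        ]
        occupied: dict[str, list[tuple[int, int]]] = {}
        for p in promoters:
            occupied.setdefault(p.chrom, []).append((p.start, p.end))
        for key in peaks:
            placed = 0
            attempts = 0
            while placed < spec.n_decoy_peaks and attempts < spec.n_decoy_peaks * 50:
                attempts += 1
                chrom, size = chroms[int(rng.integers(0, len(chroms)))]
                start = int(rng.integers(0, size - 1000))
                iv = (start, start + int(rng.integers(200, 1000)))
                if any(
                    iv[0] < e and s < iv[1] for s, e in occupied.get(chrom, [])
                ):
                    continue
                peaks[key].append(
                    Peak(
                        GenomicInterval(chrom, iv[0], iv[1]),
                        mark=key[0],
                        condition=key[1],
                    )
                )
                placed += 1
    return peaks, truth_groups, truth_states


def generate_expression(
    truth_groups: Mapping[str, TransitionGroup],
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Two-condition FPKM table with a planted Group I repression.

    Baseline condition-A FPKM is log-normal (long-tailed, positive).
    Condition B multiplies by 2^(s*(noise magnitude + planted effect))
    where the sign s is down with probability
    ``repression_prob_group_I`` for Group I genes and 1/2 otherwise.
    With ``effect_scale == 0`` every gene is pure symmetric noise
    (null model).
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed + 2)
    genes = sorted(truth_groups.keys())
    n = len(genes)
    baseline = rng.lognormal(mean=2.0, sigma=1.2, size=n)
    noise_mag = np.abs(rng.normal(0.0, spec.expression_noise_sd, size=n))
    effect_mag = np.abs(rng.normal(0.0, 1.0, size=n))
    u_sign = rng.random(n)

    values_b = np.empty(n)
    for i, gene in enumerate(genes):
        group = truth_groups[gene]
        if spec.effect_scale > 0 and group is TransitionGroup.I:
            p_down = spec.repression_prob_group_I
            magnitude = noise_mag[i] + spec.effect_scale * effect_mag[i]
        else:
            p_down = 0.5
            magnitude = noise_mag[i]
        sign = -1.0 if u_sign[i] < p_down else 1.0
        # keep a strict inequality in the planted direction
        magnitude = max(magnitude, 1e-6)
        values_b[i] = baseline[i] * 2.0 ** (sign * magnitude)

    return pd.DataFrame(
        {spec.condition_a: baseline, spec.condition_b: values_b}, index=genes
    ).rename_axis("gene_id")


def generate_cohort(
    geneset: Sequence[str],
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
    n_background_genes: int = 200,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort expression matrix with a planted TN gene-set depression.

    Returns (matrix genes x samples, metadata with ER/PR/HER2 and a
    TN/Non-TN truth column). Gene-set genes in TN-like samples are
    shifted down by ``spec.cohort_delta`` (additive, on the expression
    scale) before truncation at 0.
    """
    if spec.n_tn + spec.n_non_tn < 4:
        raise ValueError("cohort needs at least 4 samples")
    rng = rng if rng is not None else np.random.default_rng(spec.seed + 3)
    genes = list(geneset) + [f"BG{i:04d}" for i in range(n_background_genes)]
    samples = [f"TN{i:03d}" for i in range(spec.n_tn)] + [
        f"NT{i:03d}" for i in range(spec.n_non_tn)
    ]
    base_mean = rng.uniform(5.0, 15.0, size=len(genes))
    matrix = (
        base_mean[:, None]
        + rng.normal(0.0, spec.cohort_noise_sd, size=(len(genes), len(samples)))
    )
    gene_in_set = np.array([g in set(geneset) for g in genes])
    tn_mask = np.array([s.startswith("TN") for s in samples])
    matrix[np.ix_(gene_in_set, tn_mask)] -= spec.cohort_delta
    matrix = np.clip(matrix, 0.0, None)
    df = pd.DataFrame(matrix, index=genes, columns=samples).rename_axis("gene_id")

    rows = []
    for s in samples:
        if s.startswith("TN"):
            er = pr = her2 = "negative"
            label = "TN"
        else:
            statuses = ["negative", "negative", "negative"]
            # at least one definitively positive receptor
            statuses[int(rng.integers(0, 3))] = "positive"
            for j in range(3):
                if statuses[j] == "negative" and rng.random() < 0.3:
                    statuses[j] = "positive"
            er, pr, her2 = statuses
            label = "NON_TN"
        rows.append(
            {"sample_id": s, "ER": er, "PR": pr, "HER2": her2, "truth_label": label}
        )
    meta = pd.DataFrame(rows)
    return df, meta


def generate_ontology(
    truth_groups: Mapping[str, TransitionGroup],
    rng: np.random.Generator | None = None,
    n_random_terms: int = 20,
    planted_term_id: str = "TERM:ADHESION",
) -> list[TermAnnotation]:
    """Term ontology with one term over-populated by Group I genes."""
    rng = rng if rng is not None else np.random.default_rng(7)
    genes = sorted(truth_groups.keys())
    group_i = [g for g in genes if truth_groups[g] is TransitionGroup.I]
    others = [g for g in genes if truth_groups[g] is not TransitionGroup.I]
    n_from_group = max(1, int(0.6 * len(group_i)))
    planted_members = list(
        rng.choice(group_i, size=min(n_from_group, len(group_i)), replace=False)
    ) + list(rng.choice(others, size=min(20, len(others)), replace=False))
    terms = [
        TermAnnotation(
            planted_term_id, "cell-cell adhesion (planted)", frozenset(planted_members)
        )
    ]
    for t in range(n_random_terms):
        size = int(rng.integers(10, max(11, len(genes) // 10)))
        members = rng.choice(genes, size=min(size, len(genes)), replace=False)
        terms.append(
            TermAnnotation(f"TERM:{t:04d}", f"random term {t}", frozenset(members))
        )
    return terms


def generate_ct_tables(
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
    planted_folds: Mapping[str, Mapping[str, float]] | None = None,
    noise_sd: float = 0.05,
    n_replicates: int = 3,
    reference: str = "GAPDH",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """RT-PCR and ChIP-qPCR Ct tables with planted fold changes.

    ``planted_folds`` maps gene -> {sample label -> fold relative to
    the control sample}; Ct shift is -log2(fold) on the target with
    Gaussian replicate noise. Returns (rt_table, rt_truth, chip_table).
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed + 4)
    if planted_folds is None:
        planted_folds = {
            "GENE_A": {"cond": 0.25},
            "GENE_B": {"cond": 1.0},
            "GENE_C": {"cond": 4.0},
        }
    rows = []
    truth_rows = []
    samples = sorted({s for folds in planted_folds.values() for s in folds})
    base_ref_ct = 18.0
    for sample in ["control"] + samples:
        for rep in range(1, n_replicates + 1):
            rows.append(
                {
                    "target": reference,
                    "sample": sample,
                    "replicate": rep,
                    "ct": base_ref_ct + float(rng.normal(0, noise_sd)),
                }
            )
    for gene, folds in planted_folds.items():
        base_ct = float(rng.uniform(22.0, 28.0))
        for rep in range(1, n_replicates + 1):
            rows.append(
                {
                    "target": gene,
                    "sample": "control",
                    "replicate": rep,
                    "ct": base_ct + float(rng.normal(0, noise_sd)),
                }
            )
        for sample, fold in folds.items():
            shifted = base_ct - math.log2(fold)
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {
                        "target": gene,
                        "sample": sample,
                        "replicate": rep,
                        "ct": shifted + float(rng.normal(0, noise_sd)),
                    }
                )
            truth_rows.append({"gene": gene, "sample": sample, "fold": fold})
    rt_table = pd.DataFrame(rows)
    rt_truth = pd.DataFrame(truth_rows)

    chip_rows = []
    for condition, k27_percent in (("epithelial", 2.0), ("mesenchymal", 4.8)):
        input_ct = 20.0
        for antibody, percent in (
            ("target_mark", k27_percent),
            ("total_H3", 40.0),
            ("IgG", 0.1),
        ):
            # percent input -> IP Ct given a 1% input aliquot
            adjusted_input = input_ct - math.log2(100.0)
            ct_ip = adjusted_input - math.log2(percent / 100.0)
            chip_rows.append(
                {
                    "locus": "PROMOTER_1",
                    "antibody": antibody,
                    "condition": condition,
                    "ct": ct_ip + float(rng.normal(0, noise_sd)),
                    "input_fraction": 0.01,
                }
            )
        chip_rows.append(
            {
                "locus": "PROMOTER_1",
                "antibody": "input",
                "condition": condition,
                "ct": input_ct + float(rng.normal(0, noise_sd)),
                "input_fraction": 0.01,
            }
        )
    chip_table = pd.DataFrame(chip_rows)
    return rt_table, rt_truth, chip_table


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate every component of a planted synthetic dataset."""
    rng = np.random.default_rng(spec.seed)
    annotation = generate_annotation(spec, rng)
    peaks, truth_groups, truth_states = generate_condition_peaks(
        annotation, spec, rng
    )
    expression = generate_expression(truth_groups, spec, rng)
    group_i = sorted(
        g for g, grp in truth_groups.items() if grp is TransitionGroup.I
    )
    cohort_matrix, cohort_meta = generate_cohort(group_i, spec, rng)
    ontology = generate_ontology(truth_groups, rng)
    rt_table, rt_truth, chip_table = generate_ct_tables(spec, rng)
    return SyntheticDataset(
        spec=spec,
        annotation=annotation,
        peaks=peaks,
        truth_groups=truth_groups,
        truth_states=truth_states,
        expression=expression,
        cohort_matrix=cohort_matrix,
        cohort_metadata=cohort_meta,
        ontology=ontology,
        rt_ct_table=rt_table,
        rt_truth=rt_truth,
        chip_table=chip_table,
    )


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write a dataset in the formats the pipeline consumes.

    Emits gene BED, per-(mark, condition) peak BEDs, expression TSVs,
    cohort TSVs, a GMT ontology, Ct TSVs and a truth TSV. Returns the
    written paths keyed by role.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    genes_path = outdir / "genes.bed"
    with open(genes_path, "w") as handle:
        for g in dataset.annotation:
            b = g.body
            handle.write(
                f"{b.chrom}\t{b.start}\t{b.end}\t{g.gene_id}\t0\t{b.strand}\n"
            )
    paths["genes"] = genes_path

    for (mark, cond), peak_list in sorted(dataset.peaks.items()):
        p = outdir / f"peaks_{mark}_{cond}.bed"
        write_bed(peak_list, p)
        paths[f"peaks_{mark}_{cond}"] = p

    expr_path = outdir / "expression.tsv"
    dataset.expression.to_csv(expr_path, sep="\t")
    paths["expression"] = expr_path

    cohort_path = outdir / "cohort_matrix.tsv"
    dataset.cohort_matrix.to_csv(cohort_path, sep="\t")
    paths["cohort_matrix"] = cohort_path
    meta_path = outdir / "cohort_metadata.tsv"
    dataset.cohort_metadata.to_csv(meta_path, sep="\t", index=False)
    paths["cohort_metadata"] = meta_path

    gmt_path = outdir / "ontology.gmt"
    write_gmt(dataset.ontology, gmt_path)
    paths["ontology"] = gmt_path

    rt_path = outdir / "rt_ct.tsv"
    dataset.rt_ct_table.to_csv(rt_path, sep="\t", index=False)
    paths["rt_ct"] = rt_path
    chip_path = outdir / "chip_ct.tsv"
    dataset.chip_table.to_csv(chip_path, sep="\t", index=False)
    paths["chip_ct"] = chip_path

    truth_path = outdir / "truth_groups.tsv"
    with open(truth_path, "w") as handle:
        handle.write("gene_id\tgroup\tstate_a\tstate_b\n")
        for gene_id in sorted(dataset.truth_groups):
            sa, sb = dataset.truth_states[gene_id]
            handle.write(
                f"{gene_id}\t{dataset.truth_groups[gene_id].value}\t"
                f"{sa.value}\t{sb.value}\n"
            )
    paths["truth"] = truth_path

    sig_path = outdir / "reference_signature.txt"
    # reference signature: planted to overlap Groups II and IV most
    rng = np.random.default_rng(dataset.spec.seed + 5)
    sig = []
    for gene_id, group in sorted(dataset.truth_groups.items()):
        prob = {
            TransitionGroup.I: 0.15,
            TransitionGroup.II: 0.6,
            TransitionGroup.III: 0.3,
            TransitionGroup.IV: 0.7,
            TransitionGroup.NONE: 0.05,
        }[group]
        if rng.random() < prob:
            sig.append(gene_id)
    with open(sig_path, "w") as handle:
        handle.write("\n".join(sig) + "\n")
    paths["signature"] = sig_path
    return paths
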