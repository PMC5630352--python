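"""qPCR and ChIP-qPCR calculators.

Deterministic arithmetic for cycle-threshold readouts: comparative-Ct
fold changes (2^-ddCt), Holm-Sidak step-down adjustment, the
three-criterion reactivation call, percent-input quantification with
input-fraction adjustment, H3-normalized enrichment with IgG
background subtraction, and simple condition fold enrichment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class CtMeasurement:
    """One qPCR cycle-threshold observation."""

    target: str
    sample: str
    replicate: int
    ct: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.ct) or self.ct <= 0:
            raise ValueError(f"ct must be finite and positive, got {self.ct}")


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a Ct TSV with columns target, sample, replicate, ct."""
    df = pd.read_csv(path, sep="\t")
    required = {"target", "sample", "replicate", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    bad = df.index[~np.isfinite(df["ct"]) | (df["ct"] <= 0)]
    if len(bad):
        # +2 converts to 1-based file line numbers under the header
        lines = [int(i) + 2 for i in bad[:5]]
        raise ValueError(f"invalid ct values at lines {lines}")
    return df


def mean_ct(measurements: Iterable[CtMeasurement]) -> dict[tuple[str, str], float]:
    """Arithmetic mean Ct per (target, sample) across replicates."""
    sums: dict[tuple[str, str], list[float]] = {}
    for m in measurements:
        sums.setdefault((m.target, m.sample), []).append(m.ct)
    return {key: sum(v) / len(v) for key, v in sums.items()}


def delta_delta_ct(
    ct_target_cond: float,
    ct_ref_cond: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Comparative-Ct fold change 2^-ddCt.

    dCt = Ct(target) - Ct(reference) per sample; ddCt is the
    condition-minus-control difference of dCt. Replicates must be
    averaged per (target, sample) beforehand.
    """
    for ct in (ct_target_cond, ct_ref_cond, ct_target_ctrl, ct_ref_ctrl):
        if not math.isfinite(ct):
            raise ValueError("all four Ct values must be finite")
    ddct = (ct_target_cond - ct_ref_cond) - (ct_target_ctrl - ct_ref_ctrl)
    return 2.0 ** (-ddct)


def fold_change_from_ct_table(
    table: pd.DataFrame,
    target: str,
    condition: str,
    control: str,
    reference: str = "GAPDH",
) -> float:
    """2^-ddCt for one target between two sample labels, from a Ct table."""
    means = {
        (t, s): g["ct"].mean() for (t, s), g in table.groupby(["target", "sample"])
    }
    try:
        return delta_delta_ct(
            means[(target, condition)],
            means[(reference, condition)],
            means[(target, control)],
            means[(reference, control)],
        )
    except KeyError as exc:
        raise ValueError(
            f"missing Ct measurements for {exc.args[0]} "
            f"(target={target}, reference={reference})"
        ) from None


def holm_sidak_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm-Sidak step-down adjusted p-values, in the input order.

    Sorted ascending, adjusted_(i) = 1 - (1 - p_(i))^(m - i + 1) with
    running-maximum monotonicity enforcement and a cap at 1.
    """
    p = list(p_values)
    for value in p:
        if not (0.0 <= value <= 1.0):
            raise ValueError(f"p-value out of [0, 1]: {value}")
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running = 0.0
    for rank, idx in enumerate(order):
        adj = 1.0 - (1.0 - p[idx]) ** (m - rank)
        running = max(running, adj)
        adjusted[idx] = min(running, 1.0)
    return adjusted


@dataclass(frozen=True)
class ComparisonResult:
    """One tested expression comparison: adjusted p and direction."""

    p_adjusted: float
    direction: float  # sign of (second condition - first condition)


@dataclass(frozen=True)
class ReactivationCall:
    gene: str
    down_in_emt: bool
    up_in_met: bool
    blocked_by_inhibitor: bool

    @property
    def full_pattern(self) -> bool:
        return self.down_in_emt and self.up_in_met and self.blocked_by_inhibitor


def met_reactivation_call(
    gene: str,
    down: ComparisonResult,
    up: ComparisonResult,
    block: ComparisonResult,
    alpha: float = 0.05,
) -> ReactivationCall:
    """Three-criterion call for inhibitor-sensitive reactivation.

    ``down``: induction vs vehicle -- called when significant and the
    induced condition is lower. ``up``: withdrawal vs induction --
    called when significant and higher after withdrawal. ``block``:
    inhibitor vs vehicle during withdrawal -- called when significant
    and lower under the inhibitor. The full pattern requires all three.
    """
    for comparison in (down, up, block):
        if comparison is None:
            raise ValueError(f"gene {gene}: missing comparison")
    return ReactivationCall(
        gene=gene,
        down_in_emt=down.p_adjusted < alpha and down.direction < 0,
        up_in_met=up.p_adjusted < alpha and up.direction > 0,
        blocked_by_inhibitor=block.p_adjusted < alpha and block.direction < 0,
    )


def percent_input(ct_ip: float, ct_input: float, input_fraction: float) -> float:
    """ChIP signal as percent of input chromatin.

    The input Ct is first adjusted for the fraction of chromatin used
    as input (adjusted = ct_input - log2(1/fraction)), then
    percent = 100 * 2^(adjusted_input - ct_ip).
    """
    if not (0.0 < input_fraction <= 1.0):
        raise ValueError(f"input_fraction must be in (0, 1], got {input_fraction}")
    adjusted_input = ct_input - math.log2(1.0 / input_fraction)
    return 100.0 * 2.0 ** (adjusted_input - ct_ip)


def h3_normalized_enrichment(
    signal_target: float,
    signal_h3: float,
    signal_igg: float,
    mode: str = "subtract_before",
) -> tuple[float, bool]:
    """Target ChIP signal normalized to total-H3 after IgG subtraction.

    "subtract_before" (default) removes the IgG background from both
    the target and H3 signals before dividing; "subtract_after"
    divides both by H3 first and then subtracts. Negative numerators
    are floored at 0 and flagged. Returns (value, floored flag).
    """
    if signal_h3 <= signal_igg:
        raise ValueError(
            "H3 signal must exceed IgG background for normalization "
            f"(H3={signal_h3}, IgG={signal_igg})"
        )
    if mode == "subtract_before":
        numerator = signal_target - signal_igg
        value = numerator / (signal_h3 - signal_igg)
    elif mode == "subtract_after":
        numerator = signal_target - signal_igg
        value = signal_target / signal_h3 - signal_igg / signal_h3
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if value < 0:
        return 0.0, True
    return value, False


def fold_enrichment(value_b: float, value_a: float) -> float:
    """Ratio of an enrichment value between two conditions (B over A)."""
    if value_a <= 0:
        raise ValueError(f"fold enrichment undefined for reference {value_a}")
    return value_b / value_a


def _welch_from_replicates(x: np.ndarray, y: np.ndarray) -> float:
    from bivtrans.expression_analysis import welch_t_test

    _, _, p = welch_t_test(x, y)
    return p


def analyze_reactivation_panel(
    ct_table: pd.DataFrame,
    comparisons: Mapping[str, tuple[str, str]],
    reference: str = "GAPDH",
    alpha: float = 0.05,
    family: str = "per_panel",
) -> pd.DataFrame:
    """Run the three-comparison reactivation analysis on a Ct table.

    ``comparisons`` maps the comparison names "down", "up" and "block"
    to (control_sample, condition_sample) label pairs. For each target
    gene and comparison, replicate dCt values (Ct_target - mean
    Ct_reference per sample) are compared with an unpaired two-sided
    t-test; p-values are Holm-Sidak adjusted within the configured
    family ("per_panel" pools all genes of a comparison, "per_gene"
    adjusts the three comparisons of each gene together). Genes missing
    a comparison are excluded with a logged reason.

    Returns a per-gene DataFrame with fold changes, adjusted p-values,
    the three criterion booleans and the full-pattern flag.
    """
    import logging

    logger = logging.getLogger(__name__)
    required = {"down", "up", "block"}
    if set(comparisons) != required:
        raise ValueError(f"comparisons must be exactly {sorted(required)}")

    ref_means = {
        s: g["ct"].mean()
        for s, g in ct_table[ct_table["target"] == reference].groupby("sample")
    }
    targets = sorted(t for t in ct_table["target"].unique() if t != reference)

    raw: dict[str, dict[str, tuple[float, float, float]]] = {}
    usable: list[str] = []
    for gene in targets:
        gene_rows = ct_table[ct_table["target"] == gene]
        per_comp: dict[str, tuple[float, float, float]] = {}
        ok = True
        for name, (ctrl, cond) in comparisons.items():
            ctrl_ct = gene_rows[gene_rows["sample"] == ctrl]["ct"].to_numpy()
            cond_ct = gene_rows[gene_rows["sample"] == cond]["ct"].to_numpy()
            if (
                len(ctrl_ct) < 2
                or len(cond_ct) < 2
                or ctrl not in ref_means
                or cond not in ref_means
            ):
                logger.info("gene %s excluded: incomplete %s comparison", gene, name)
                ok = False
                break
            dct_ctrl = ctrl_ct - ref_means[ctrl]
            dct_cond = cond_ct - ref_means[cond]
            p = _welch_from_replicates(dct_cond, dct_ctrl)
            fold = 2.0 ** (-(dct_cond.mean() - dct_ctrl.mean()))
            # direction of expression change: fold > 1 means higher
            direction = 1.0 if fold > 1.0 else (-1.0 if fold < 1.0 else 0.0)
            per_comp[name] = (fold, p, direction)
        if ok:
            raw[gene] = per_comp
            usable.append(gene)

    adjusted: dict[tuple[str, str], float] = {}
    if family == "per_panel":
        for name in required:
            genes = usable
            adj = holm_sidak_adjust([raw[g][name][1] for g in genes]) if genes else []
            for g, a in zip(genes, adj):
                adjusted[(g, name)] = a
    elif family == "per_gene":
        for g in usable:
            names = sorted(required)
            adj = holm_sidak_adjust([raw[g][n][1] for n in names])
            for n, a in zip(names, adj):
                adjusted[(g, n)] = a
    else:
        raise ValueError(f"unknown family {family!r}")

    rows = []
    for gene in usable:
        comps = {
            name: ComparisonResult(adjusted[(gene, name)], raw[gene][name][2])
            for name in required
        }
        call = met_reactivation_call(
            gene, comps["down"], comps["up"], comps["block"], alpha=alpha
        )
        rows.append(
            {
                "gene": gene,
                "fold_down": raw[gene]["down"][0],
                "p_down": adjusted[(gene, "down")],
                "fold_up": raw[gene]["up"][0],
                "p_up": adjusted[(gene, "up")],
                "fold_block": raw[gene]["block"][0],
                "p_block": adjusted[(gene, "block")],
                "down_in_emt": call.down_in_emt,
                "up_in_met": call.up_in_met,
                "blocked_by_inhibitor": call.blocked_by_inhibitor,
                "full_pattern": call.full_pattern,
            }
        )
    return pd.DataFrame(rows).set_index("gene") if rows else pd.DataFrame(
        columns=[
            "fold_down", "p_down", "fold_up", "p_up", "fold_block", "p_block",
            "down_in_emt", "up_in_met", "blocked_by_inhibitor", "full_pattern",
        ]
    )
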