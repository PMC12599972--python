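"""Bulk-expression logic.

Maternal/zygotic transcript segregation from a 0-hpf timecourse column,
zygotic log fold-change timecourses, localized-gene selection from germ-layer
dissection DE tables, direct-target calling from knockdown DE plus peak
assignments, and the delta-delta-Cp qPCR fold-change method.

Sign conventions: the ``log2fc`` column of a knockdown table is
morphant-over-wild-type, so a gene *activated* by the factor goes down in the
morphant (log2fc <= -1 at the default 2-fold threshold) and a *repressed*
gene goes up (log2fc >= +1).  Localization tables are layer-A-over-layer-B.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .peaktools import PeakGeneAssignment

__all__ = [
    "classify_maternal_zygotic",
    "zygotic_logfc",
    "select_localized_genes",
    "TargetCall",
    "call_direct_targets",
    "intersect_target_sets",
    "DdcpResult",
    "ddcp_fold_change",
]


def classify_maternal_zygotic(
    tc: pd.DataFrame, maternal_threshold: float = 1.0, t0_col: str = "0"
) -> tuple[list[str], list[str]]:
    """Partition genes into (maternal, zygotic) on the 0-hpf TPM column.

    A gene is maternal iff its 0-hpf TPM is at least ``maternal_threshold``
    (default 1 TPM); everything else is zygotic.  The two lists partition the
    table's index.
    """
    if t0_col not in tc.columns:
        raise ConfigError(f"timecourse lacks the 0-hpf column {t0_col!r}")
    t0 = tc[t0_col]
    maternal = list(tc.index[t0 >= maternal_threshold])
    zygotic = list(tc.index[t0 < maternal_threshold])
    return maternal, zygotic


def zygotic_logfc(
    tc: pd.DataFrame, pseudocount: float = 0.1, t0_col: str = "0"
) -> pd.DataFrame:
    """Per-gene log2 fold change of each timepoint against 0 hpf.

    ``log2((TPM_t + pseudocount) / (TPM_0 + pseudocount))``; the pseudocount
    keeps unexpressed maternal baselines finite.
    """
    if t0_col not in tc.columns:
        raise ConfigError(f"timecourse lacks the 0-hpf column {t0_col!r}")
    base = tc[t0_col] + pseudocount
    out = {}
    for col in tc.columns:
        if col == t0_col:
            continue
        out[col] = np.log2((tc[col] + pseudocount) / base)
    return pd.DataFrame(out, index=tc.index)


def select_localized_genes(
    de: pd.DataFrame,
    zygotic_set: list[str],
    fc_threshold: float = 2.0,
    top_n: int = 250,
) -> dict[str, list[str]]:
    """Top zygotic genes enriched on each side of a germ-layer comparison.

    Keeps zygotic genes with ``|log2fc| >= log2(fc_threshold)``, splits them
    by sign, ranks each side by FDR ascending (ties: larger ``|log2fc|``
    first, then gene id) and truncates to ``top_n``.  Returns
    ``{"up": [...], "down": [...]}`` in that ranked order.
    """
    for col in ("log2fc", "fdr"):
        if col not in de.columns:
            raise ConfigError(f"DE table lacks required column {col!r}")
    log2_thresh = math.log2(fc_threshold)
    zset = set(zygotic_set)
    kept = de[de.index.isin(zset) & (de["log2fc"].abs() >= log2_thresh)].copy()
    kept["_abs_lfc"] = kept["log2fc"].abs()
    kept["_gene"] = kept.index.astype(str)
    out = {}
    for side, mask in (("up", kept["log2fc"] > 0), ("down", kept["log2fc"] < 0)):
        side_df = kept[mask].sort_values(
            ["fdr", "_abs_lfc", "_gene"], ascending=[True, False, True]
        )
        out[side] = list(side_df.index[:top_n])
    return out


@dataclass(frozen=True)
class TargetCall:
    """A direct-target call: DE evidence plus a supporting bound region."""

    gene_id: str
    direction: str  # "activated" | "repressed"
    log2fc: float
    fdr: float | None
    peaks: tuple[tuple[int, int], ...]  # (peak index, distance) pairs


def call_direct_targets(
    de: pd.DataFrame,
    assignments: PeakGeneAssignment,
    fc_threshold: float = 2.0,
) -> list[TargetCall]:
    """Direct targets: >= ``fc_threshold``-fold change and a peak in window.

    With the morphant-over-WT convention, ``log2fc <= -log2(fc_threshold)``
    yields an "activated" call and ``>= +log2(fc_threshold)`` a "repressed"
    call, each requiring >= 1 assigned peak.  The two lists are disjoint by
    construction.
    """
    if "log2fc" not in de.columns:
        raise ConfigError("DE table lacks required column 'log2fc'")
    log2_thresh = math.log2(fc_threshold)
    calls: list[TargetCall] = []
    for gene_id, row in de.iterrows():
        peaks = assignments.gene_to_peaks.get(gene_id)
        if not peaks:
            continue
        lfc = float(row["log2fc"])
        if lfc <= -log2_thresh:
            direction = "activated"
        elif lfc >= log2_thresh:
            direction = "repressed"
        else:
            continue
        fdr = float(row["fdr"]) if "fdr" in de.columns else None
        calls.append(
            TargetCall(str(gene_id), direction, lfc, fdr, tuple(peaks))
        )
    return calls


def intersect_target_sets(
    a: list[TargetCall], b: list[TargetCall]
) -> dict[str, list[TargetCall]]:
    """Split two target lists into joint, a-only and b-only calls.

    A call is *joint* when the same gene is called in the same direction in
    both lists; a gene called in opposite directions appears in both "only"
    sets, each with its own direction.
    """
    keys_a = {(c.gene_id, c.direction) for c in a}
    keys_b = {(c.gene_id, c.direction) for c in b}
    joint_keys = keys_a & keys_b
    return {
        "joint": [c for c in a if (c.gene_id, c.direction) in joint_keys],
        "a_only": [c for c in a if (c.gene_id, c.direction) not in joint_keys],
        "b_only": [c for c in b if (c.gene_id, c.direction) not in joint_keys],
    }


@dataclass
class DdcpResult:
    """Delta-delta-Cp fold change with replicate spread and a t-test p."""

    fold: float
    ddcp: float
    sd: float | None
    p: float | None
    flagged: bool  # True when < 2 replicates per arm left sd/p undefined


def ddcp_fold_change(
    cp_target_treatment: np.ndarray,
    cp_reference_treatment: np.ndarray,
    cp_target_control: np.ndarray,
    cp_reference_control: np.ndarray,
) -> DdcpResult:
    """Fold change between treatment and control by the delta-delta-Cp method.

    Per replicate, ``dCp = Cp_target - Cp_reference``; then
    ``ddCp = mean(dCp_treatment) - mean(dCp_control)`` and the fold change is
    ``2**(-ddCp)``.  The sd is the sample sd of per-treatment-replicate fold
    changes ``2**-(dCp_t,i - mean(dCp_control))`` and the p-value comes from a
    two-sample two-tailed t test on the replicate dCp values.  With fewer
    than 2 replicates in either arm, sd and p are unavailable and flagged.
    """
    dcp_t = np.asarray(cp_target_treatment, dtype=float) - np.asarray(
        cp_reference_treatment, dtype=float
    )
    dcp_c = np.asarray(cp_target_control, dtype=float) - np.asarray(
        cp_reference_control, dtype=float
    )
    if dcp_t.size == 0 or dcp_c.size == 0:
        raise ConfigError("both arms need at least one replicate")
    if not (np.all(np.isfinite(dcp_t)) and np.all(np.isfinite(dcp_c))):
        raise ConfigError("non-finite quantification cycles")
    ddcp = float(np.mean(dcp_t) - np.mean(dcp_c))
    fold = float(2.0**-ddcp)
    if dcp_t.size < 2 or dcp_c.size < 2:
        return DdcpResult(fold, ddcp, None, None, flagged=True)
    rep_folds = 2.0 ** -(dcp_t - np.mean(dcp_c))
    sd = float(np.std(rep_folds, ddof=1))
    if np.var(dcp_t) == 0 and np.var(dcp_c) == 0:
        # degenerate replicate-free spread: identical means are a perfect
        # null, different means an exact separation
        p = 1.0 if ddcp == 0 else 0.0
    else:
        p = float(stats.ttest_ind(dcp_t, dcp_c).pvalue)
    return DdcpResult(fold, ddcp, sd, p, flagged=False)
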