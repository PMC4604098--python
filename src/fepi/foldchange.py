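"""Replicate-wise fold changes, DEG-list overlap, fold filtering and the
four-way regulatory classification.

The central object is the *overlap table*: one row per gene that responded to
both iron (Fe) deficiency and phosphate (Pi) starvation, carrying a
treatment/control fold change (mean ± SD over paired biological replicates)
for each contrast.  Genes whose control replicates were all zero while at
least one treatment replicate was positive cannot be given a finite ratio;
these carry an UNDETERMINED fold, rendered "-" in tabular output, and are
treated as up-regulated wherever a direction is needed.

Regulatory types partition the overlap genes by direction of response:

====  ====================  ====================
type  Fe deficiency         Pi starvation
====  ====================  ====================
1     down (fold < 1)       down (fold < 1)
2     up   (fold > 1)       up   (fold > 1)
3     down                  up
4     up                    down
====  ====================  ====================

A fold of exactly 1 in either contrast leaves the gene UNCLASSIFIED.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "UNCLASSIFIED",
    "FoldChangeRecord",
    "compute_fold_change",
    "fold_change_table",
    "overlap_genes",
    "build_overlap_table",
    "filter_by_fold",
    "classify_types",
    "type_subcounts",
    "qpcr_relative_expression",
    "load_published_foldchanges",
    "read_overlap_table",
    "write_overlap_table",
]

#: Sentinel type label for genes with a fold change of exactly 1.
UNCLASSIFIED = 0


@dataclass(frozen=True)
class FoldChangeRecord:
    """Per-gene fold change for one contrast.

    mean_fold/sd_fold are ``None`` when the fold is undetermined: every
    control replicate was zero.  ``silent`` additionally marks the degenerate
    case where both conditions were entirely zero.  ``sd_fold`` is also
    ``None`` when only a single usable replicate pair remains.
    """

    gene: str
    mean_fold: float | None
    sd_fold: float | None
    n_reps: int
    undetermined: bool = False
    silent: bool = False

    def __post_init__(self) -> None:
        if not self.undetermined:
            if self.mean_fold is None or self.mean_fold <= 0:
                raise ValueError(f"{self.gene}: mean_fold must be positive")
            if self.sd_fold is not None and self.sd_fold < 0:
                raise ValueError(f"{self.gene}: sd_fold must be non-negative")

    @property
    def is_up(self) -> bool:
        """Direction used by the classifier; undetermined counts as up."""
        return self.undetermined or self.mean_fold > 1


def compute_fold_change(
    treatment: Sequence[float],
    control: Sequence[float],
    gene: str = "",
) -> FoldChangeRecord:
    """Mean ± sample SD of the paired per-replicate ratios treatment/control.

    Replicates are paired by index.  Conventions for zero controls:

    * all control replicates zero, any treatment positive -> UNDETERMINED
      (rendered "-"); no finite ratio exists,
    * all replicates zero in both conditions -> UNDETERMINED and ``silent``,
    * some (not all) control replicates zero -> those pairs are dropped and
      ``n_reps`` reduced, keeping the mean and SD finite.
    """
    t = np.asarray(treatment, dtype=float)
    c = np.asarray(control, dtype=float)
    if t.shape != c.shape or t.ndim != 1 or t.size == 0:
        raise ValueError("treatment and control need equal replicate counts")
    if (t < 0).any() or (c < 0).any():
        raise ValueError("abundances must be non-negative")
    if (c == 0).all():
        silent = bool((t == 0).all())
        return FoldChangeRecord(gene, None, None, t.size,
                                undetermined=True, silent=silent)
    keep = c > 0
    ratios = t[keep] / c[keep]
    n = int(keep.sum())
    sd = float(np.std(ratios, ddof=1)) if n > 1 else None
    return FoldChangeRecord(gene, float(ratios.mean()), sd, n)


def fold_change_table(
    treatment: pd.DataFrame, control: pd.DataFrame
) -> dict[str, FoldChangeRecord]:
    """Apply :func:`compute_fold_change` gene-wise to two replicate tables.

    Both frames are genes x replicates with identical indexes.
    """
    if not treatment.index.equals(control.index):
        raise ValueError("treatment and control tables index different genes")
    return {
        g: compute_fold_change(treatment.loc[g].to_numpy(),
                               control.loc[g].to_numpy(), gene=g)
        for g in treatment.index
    }


def overlap_genes(list_a: Iterable[str], list_b: Iterable[str]) -> list[str]:
    """Sorted intersection of two DEG lists."""
    return sorted(set(list_a) & set(list_b))


def build_overlap_table(
    fe: Mapping[str, FoldChangeRecord],
    pi: Mapping[str, FoldChangeRecord],
    genes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Assemble the two-contrast overlap table.

    ``genes`` defaults to the intersection of the two record sets.  Columns:
    fe_mean, fe_sd, pi_mean, pi_sd (NaN where undetermined/absent) and the
    boolean flags fe_undetermined, pi_undetermined, fe_silent, pi_silent.
    """
    if genes is None:
        genes = overlap_genes(fe.keys(), pi.keys())
    rows = []
    for g in genes:
        if g not in fe or g not in pi:
            raise KeyError(f"gene {g} lacks a record in one contrast")
        a, b = fe[g], pi[g]
        rows.append({
            "fe_mean": np.nan if a.undetermined else a.mean_fold,
            "fe_sd": np.nan if a.sd_fold is None else a.sd_fold,
            "pi_mean": np.nan if b.undetermined else b.mean_fold,
            "pi_sd": np.nan if b.sd_fold is None else b.sd_fold,
            "fe_undetermined": a.undetermined,
            "pi_undetermined": b.undetermined,
            "fe_silent": a.silent,
            "pi_silent": b.silent,
        })
    return pd.DataFrame(rows, index=pd.Index(list(genes), name="gene"))


def _passes(mean: float, undet: bool, cutoff: float) -> bool:
    # undetermined = zero control, positive treatment: passes any up cutoff
    if undet:
        return True
    return mean >= cutoff or mean <= 1.0 / cutoff


def filter_by_fold(table: pd.DataFrame, cutoff: float) -> pd.DataFrame:
    """Keep genes changed at least ``cutoff``-fold (up or down) in >=1 contrast."""
    if cutoff <= 1:
        raise ValueError("cutoff must exceed 1")
    keep = [
        _passes(r.fe_mean, r.fe_undetermined, cutoff)
        or _passes(r.pi_mean, r.pi_undetermined, cutoff)
        for r in table.itertuples()
    ]
    return table.loc[keep]


def classify_types(
    table: pd.DataFrame, subcount_cutoffs: Sequence[float] = ()
) -> tuple[pd.Series, dict[int, int], dict[float, dict]]:
    """Assign each overlap gene one of the four regulatory types.

    Returns ``(assignment, counts, subcounts)``: a gene -> type Series, the
    per-type totals (key 0 = UNCLASSIFIED, present only when non-empty), and
    for each requested cutoff the per-type sub-counts under both the
    "either contrast" and "both contrasts" readings of a directional
    fold-cutoff (see :func:`type_subcounts`).
    """
    labels = {}
    for r in table.itertuples():
        fe_one = (not r.fe_undetermined) and r.fe_mean == 1.0
        pi_one = (not r.pi_undetermined) and r.pi_mean == 1.0
        if fe_one or pi_one:
            labels[r.Index] = UNCLASSIFIED
            continue
        fe_up = r.fe_undetermined or r.fe_mean > 1
        pi_up = r.pi_undetermined or r.pi_mean > 1
        if fe_up and pi_up:
            labels[r.Index] = 2
        elif not fe_up and not pi_up:
            labels[r.Index] = 1
        elif pi_up:
            labels[r.Index] = 3
        else:
            labels[r.Index] = 4
    assignment = pd.Series(labels, name="type", dtype=int)
    counts = {t: int((assignment == t).sum()) for t in (1, 2, 3, 4)}
    if (assignment == UNCLASSIFIED).any():
        counts[UNCLASSIFIED] = int((assignment == UNCLASSIFIED).sum())
    subcounts = {c: type_subcounts(table, assignment, c) for c in subcount_cutoffs}
    return assignment, counts, subcounts


def type_subcounts(
    table: pd.DataFrame, assignment: pd.Series, cutoff: float
) -> dict:
    """Per-type counts of genes meeting a directional fold cutoff.

    For each gene the cutoff is applied in its type's direction per contrast
    (up -> mean >= cutoff, down -> mean <= 1/cutoff; undetermined passes up).
    Both readings are reported because "changed more than c-fold" is ambiguous
    for a two-contrast type: ``either`` requires one contrast to meet its
    directional cutoff, ``both`` requires both.
    """
    if cutoff <= 1:
        raise ValueError("cutoff must exceed 1")
    out = {"either": dict.fromkeys((1, 2, 3, 4), 0),
           "both": dict.fromkeys((1, 2, 3, 4), 0)}
    up = {1: (False, False), 2: (True, True), 3: (False, True), 4: (True, False)}
    for r in table.itertuples():
        t = int(assignment[r.Index])
        if t == UNCLASSIFIED:
            continue
        hits = []
        for mean, undet, is_up in (
            (r.fe_mean, r.fe_undetermined, up[t][0]),
            (r.pi_mean, r.pi_undetermined, up[t][1]),
        ):
            if is_up:
                hits.append(undet or mean >= cutoff)
            else:
                hits.append((not undet) and mean <= 1.0 / cutoff)
        if any(hits):
            out["either"][t] += 1
        if all(hits):
            out["both"][t] += 1
    return out


def qpcr_relative_expression(
    target_treatment: Sequence[float],
    target_control: Sequence[float],
    ref_treatment: Sequence[Sequence[float]],
    ref_control: Sequence[Sequence[float]],
) -> tuple[float, float]:
    """Relative expression and t-test p-value from qPCR threshold cycles.

    Per replicate i the normalized cycle is
    ``dCt_i = Ct_target_i - mean(Ct_ref1_i, Ct_ref2_i)`` using two reference
    genes; relative expression is ``2**(mean dCt_control - mean dCt_treatment)``
    and the p-value comes from a two-sample two-tailed Student t test on the
    replicate dCt values.  With fewer than two replicates in either group the
    p-value is undefined (NaN).
    """
    rt = np.asarray(ref_treatment, dtype=float)
    rc = np.asarray(ref_control, dtype=float)
    if rt.shape[0] != 2 or rc.shape[0] != 2:
        raise ValueError("exactly two reference genes are required")
    d_t = np.asarray(target_treatment, dtype=float) - rt.mean(axis=0)
    d_c = np.asarray(target_control, dtype=float) - rc.mean(axis=0)
    rel = float(2.0 ** (d_c.mean() - d_t.mean()))
    if d_t.size < 2 or d_c.size < 2:
        return rel, math.nan
    p = stats.ttest_ind(d_t, d_c).pvalue
    return rel, float(p)


# ---------------------------------------------------------------------------
# IO

def load_published_foldchanges() -> pd.DataFrame:
    """Packaged fold-change records for Arabidopsis root genes responding
    more than twofold to iron deficiency or phosphate starvation.

    Columns follow :func:`build_overlap_table`; "-" entries (transcript absent
    from all control replicates) become undetermined records.
    """
    src = importlib.resources.files("fepi.data") / "fe_pi_twofold_foldchanges.tsv"
    with importlib.resources.as_file(src) as path:
        raw = pd.read_csv(path, sep="\t", index_col="gene")
    undet = raw["fe_mean"] == "-"
    out = pd.DataFrame(index=raw.index)
    out["fe_mean"] = pd.to_numeric(raw["fe_mean"], errors="coerce")
    out["fe_sd"] = pd.to_numeric(raw["fe_sd"], errors="coerce")
    out["pi_mean"] = raw["pi_mean"].astype(float)
    out["pi_sd"] = raw["pi_sd"].astype(float)
    out["fe_undetermined"] = undet.to_numpy()
    out["pi_undetermined"] = False
    out["fe_silent"] = False
    out["pi_silent"] = False
    out["annotation"] = raw["annotation"]
    return out


def write_overlap_table(table: pd.DataFrame, path) -> None:
    """Write an overlap table as TSV, rendering undetermined folds as "-"."""
    out = table.copy()
    for side in ("fe", "pi"):
        undet = out[f"{side}_undetermined"]
        for col in (f"{side}_mean", f"{side}_sd"):
            out[col] = [
                "-" if u else ("" if pd.isna(v) else f"{v:.6g}")
                for v, u in zip(out[col], undet)
            ]
    cols = ["fe_mean", "fe_sd", "pi_mean", "pi_sd"]
    flags = out.apply(
        lambda r: ";".join(
            f for f in ("fe_undetermined", "pi_undetermined", "fe_silent", "pi_silent")
            if r[f]
        ),
        axis=1,
    )
    out = out[cols]
    out["flags"] = flags
    out.to_csv(path, sep="\t")


def read_overlap_table(path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_overlap_table`."""
    raw = pd.read_csv(path, sep="\t", index_col="gene", dtype=str,
                      keep_default_na=False)
    out = pd.DataFrame(index=raw.index)
    for side in ("fe", "pi"):
        out[f"{side}_mean"] = pd.to_numeric(
            raw[f"{side}_mean"].replace({"-": "", "": ""}), errors="coerce")
        out[f"{side}_sd"] = pd.to_numeric(
            raw[f"{side}_sd"].replace({"-": "", "": ""}), errors="coerce")
    flags = raw.get("flags", pd.Series("", index=raw.index))
    for f in ("fe_undetermined", "pi_undetermined", "fe_silent", "pi_silent"):
        out[f] = flags.str.contains(f).fillna(False)
    return out
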