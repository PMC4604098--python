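"""Synthetic inputs with known ground truth for every pipeline stage.

Four generators emulate the four input classes the pipeline consumes:

* :func:`gen_contrast_experiment` — per-gene, per-replicate abundance tables
  (RPKM-like) for a treatment/control contrast, with planted differentially
  expressed genes whose fold effects are drawn log-normally (symmetric in log
  space, matching the heavy right tail of real stress contrasts) and
  multiplicative replicate noise of a chosen coefficient of variation.  A
  configurable fraction of planted DEGs gets all-zero control replicates with
  positive treatment values, exercising the undetermined-fold ("-")
  convention downstream.
* :func:`gen_compendium` — a genes x arrays expression matrix with planted
  co-expression modules: genes in a module share a latent array profile with
  weight w plus independent Gaussian noise of sd s, so the expected
  within-module Pearson correlation is w**2 / (w**2 + s**2).  Callers can
  therefore plant modules above or below a network threshold.
* :func:`gen_go_universe` — a small random acyclic ontology (OBO text),
  unpropagated direct annotations, and a study list sampled with one planted
  over-represented term at stated odds.
* :func:`gen_promoters` — fixed-length upstream sequences with concrete
  motifs planted at known upstream distances; optional rejection sampling
  guarantees no background occurrence of the degenerate pattern, so a scan
  recovers exactly the planted truth.

Every generator is driven by one integer seed through its own named stream,
so adding one artifact to a run never perturbs the others, and equal seeds
give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .motif import compile_iupac, matches, PromoterRecord, P1BS

__all__ = [
    "SyntheticTruth",
    "gen_contrast_experiment",
    "gen_compendium",
    "gen_go_universe",
    "gen_promoters",
    "expected_module_r",
    "write_abundance_tsv",
    "read_abundance_tsv",
]

# stream tags keep the four artifact generators statistically independent
_STREAMS = {"contrast": 1, "compendium": 2, "ontology": 3, "promoters": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[stream], int(seed)])


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generators.

    deg_genes_per_contrast: contrast id -> {gene: fold factor (> 0)}
    module_membership: gene -> module index (genes absent are background)
    enriched_term: the ontology term planted as over-represented
    planted_motifs: gene -> list of (upstream distance, concrete k-mer)
    """

    deg_genes_per_contrast: dict[str, dict[str, float]] = field(default_factory=dict)
    module_membership: dict[str, int] = field(default_factory=dict)
    enriched_term: str | None = None
    planted_motifs: dict[str, list[tuple[int, str]]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _gene_ids(n: int, prefix: str = "G") -> list[str]:
    width = len(str(n))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def _noisy(rng: np.random.Generator, mean: np.ndarray, cv: float) -> np.ndarray:
    """Non-negative draws with the stated mean and coefficient of variation.

    Gamma-distributed multiplicative noise (shape 1/cv**2) keeps values
    positive and the expectation exact; cv = 0 returns the mean unchanged.
    """
    if cv == 0:
        return mean.copy()
    shape = 1.0 / cv**2
    return mean * rng.gamma(shape, 1.0 / shape, size=mean.shape)


def gen_contrast_experiment(
    n_genes: int,
    n_deg: int,
    fold_sampler: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    n_reps: int = 3,
    noise_cv: float = 0.1,
    zero_control_fraction: float = 0.0,
    seed: int = 0,
    contrast: str = "contrast",
    baseline_log_mean: float = 3.0,
    baseline_log_sd: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate one treatment/control contrast with planted DEGs.

    Returns ``(treatment, control, truth)``; both tables are genes x n_reps.
    Non-DEG genes share the same expected abundance in both conditions; a DEG
    with planted fold f has expected treatment/control ratio f.  The first
    ``round(zero_control_fraction * n_deg)`` planted DEGs instead get all-zero
    control replicates and strictly positive treatment values (their planted
    fold still scales the treatment mean), exercising the undetermined-fold
    convention.  ``fold_sampler(rng, k)`` defaults to lognormal(0, 1.5).
    """
    if n_genes <= 0 or n_reps <= 0:
        raise ValueError("n_genes and n_reps must be positive")
    if n_deg > n_genes or n_deg < 0:
        raise ValueError("n_deg must lie in [0, n_genes]")
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    if not 0 <= zero_control_fraction <= 1:
        raise ValueError("zero_control_fraction must lie in [0, 1]")
    rng = _rng(seed, "contrast")
    genes = _gene_ids(n_genes)
    if fold_sampler is None:
        fold_sampler = lambda r, k: r.lognormal(0.0, 1.5, size=k)

    baseline = rng.lognormal(baseline_log_mean, baseline_log_sd, size=n_genes)
    deg_idx = rng.choice(n_genes, size=n_deg, replace=False)
    folds = np.asarray(fold_sampler(rng, n_deg), dtype=float)
    if (folds <= 0).any():
        raise ValueError("fold_sampler produced non-positive folds")
    n_zero = round(zero_control_fraction * n_deg)
    zero_idx = set(deg_idx[:n_zero].tolist())

    ctrl_mean = baseline.copy()
    trt_mean = baseline.copy()
    fold_of = dict(zip(deg_idx.tolist(), folds))
    for i, f in fold_of.items():
        trt_mean[i] = baseline[i] * f
    ctrl = _noisy(rng, np.tile(ctrl_mean[:, None], (1, n_reps)), noise_cv)
    trt = _noisy(rng, np.tile(trt_mean[:, None], (1, n_reps)), noise_cv)
    for i in zero_idx:
        ctrl[i, :] = 0.0
        trt[i, :] = np.maximum(trt[i, :], np.finfo(float).tiny)

    cols = [f"rep_{j + 1}" for j in range(n_reps)]
    idx = pd.Index(genes, name="gene")
    truth = SyntheticTruth(deg_genes_per_contrast={
        contrast: {genes[i]: float(f) for i, f in sorted(fold_of.items())}
    })
    return (
        pd.DataFrame(trt, index=idx, columns=cols),
        pd.DataFrame(ctrl, index=idx, columns=cols),
        truth,
    )


def expected_module_r(latent_weight: float, noise_sd: float) -> float:
    """Expected within-module Pearson correlation of :func:`gen_compendium`."""
    return latent_weight**2 / (latent_weight**2 + noise_sd**2)


def gen_compendium(
    n_genes: int,
    n_arrays: int,
    modules: Sequence[tuple[int, float]] = (),
    noise_sd: float = 1.0,
    seed: int = 0,
    gene_ids: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Genes x arrays matrix with planted correlated modules.

    Each ``(size, latent_weight)`` module shares one standard-normal latent
    array profile scaled by ``latent_weight``; every gene adds independent
    N(0, noise_sd**2) noise, giving expected within-module correlation
    ``latent_weight**2 / (latent_weight**2 + noise_sd**2)`` (see
    :func:`expected_module_r`).  Background genes are pure noise.  Modules
    occupy the leading gene ids (pass ``gene_ids`` to control which).
    """
    if n_arrays < 3:
        raise ValueError("n_arrays must be at least 3")
    sizes = [s for s, _ in modules]
    if any(s < 2 for s in sizes):
        raise ValueError("module size must be at least 2")
    if sum(sizes) > n_genes:
        raise ValueError("module sizes exceed n_genes")
    if noise_sd <= 0:
        if noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
    rng = _rng(seed, "compendium")
    if gene_ids is not None:
        if len(gene_ids) != n_genes or len(set(gene_ids)) != n_genes:
            raise ValueError("gene_ids must be n_genes unique ids")
        genes = list(gene_ids)
    else:
        genes = _gene_ids(n_genes)
    x = noise_sd * rng.standard_normal((n_genes, n_arrays)) if noise_sd else \
        np.zeros((n_genes, n_arrays))
    membership: dict[str, int] = {}
    start = 0
    for m, (size, w) in enumerate(modules):
        latent = rng.standard_normal(n_arrays)
        for i in range(start, start + size):
            x[i] += w * latent
            membership[genes[i]] = m
        start += size
    cols = [f"array_{j + 1}" for j in range(n_arrays)]
    df = pd.DataFrame(x, index=pd.Index(genes, name="gene"), columns=cols)
    return df, SyntheticTruth(module_membership=membership)


def gen_go_universe(
    n_terms: int,
    max_depth: int,
    universe_size: int,
    study_size: int,
    enrichment_odds: float,
    planted_term: str | None = None,
    annotations_per_gene: int = 2,
    planted_term_frequency: float = 0.1,
    seed: int = 0,
) -> tuple[str, dict[str, set[str]], list[str], SyntheticTruth]:
    """Random acyclic ontology + annotations + an enriched study list.

    Returns ``(obo_text, direct_annotations, study_genes, truth)``.  The DAG
    has a single root; every other term gets one or two parents among
    shallower terms.  Direct (unpropagated) annotations assign each gene
    ``annotations_per_gene`` random non-root terms, and a fraction
    ``planted_term_frequency`` of genes is additionally annotated to the
    planted term (default: the deepest term).  Study genes are drawn without
    replacement with weight ``enrichment_odds`` for carriers of the planted
    term and 1 otherwise; odds = 1 is the null.
    """
    if n_terms < 1:
        raise ValueError("need at least one term")
    if enrichment_odds <= 0:
        raise ValueError("enrichment_odds must be positive")
    if study_size > universe_size:
        raise ValueError("study_size exceeds universe_size")
    rng = _rng(seed, "ontology")
    terms = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    depth = {terms[0]: 0}
    parents: dict[str, list[str]] = {terms[0]: []}
    for t in terms[1:]:
        eligible = [u for u in parents if depth[u] < max_depth]
        k = 1 if len(eligible) == 1 else int(rng.integers(1, 3))
        ps = sorted(rng.choice(eligible, size=min(k, len(eligible)),
                               replace=False).tolist())
        parents[t] = ps
        depth[t] = max(depth[p] for p in ps) + 1
    if planted_term is None:
        planted_term = max(terms, key=lambda t: (depth[t], t))
    if planted_term not in parents:
        raise ValueError(f"planted term {planted_term} not in generated DAG")

    stanzas = ["format-version: 1.2\nontology: synthetic-go\n"]
    for t in terms:
        lines = [f"[Term]\nid: {t}\nname: synthetic term {t[3:].lstrip('0') or 0}\n"
                 f"namespace: biological_process\n"]
        lines += [f"is_a: {p} ! parent\n" for p in parents[t]]
        stanzas.append("".join(lines))
    obo_text = "\n".join(stanzas)

    genes = _gene_ids(universe_size, prefix="SG")
    non_root = terms[1:] or terms
    direct: dict[str, set[str]] = {}
    carriers = []
    for g in genes:
        k = min(annotations_per_gene, len(non_root))
        chosen = set(rng.choice(non_root, size=k, replace=False).tolist())
        if rng.random() < planted_term_frequency:
            chosen.add(planted_term)
        direct[g] = chosen
        if planted_term in chosen:
            carriers.append(g)
    weights = np.array([enrichment_odds if g in set(carriers) else 1.0
                        for g in genes])
    weights /= weights.sum()
    study = sorted(rng.choice(genes, size=study_size, replace=False,
                              p=weights).tolist())
    truth = SyntheticTruth(enriched_term=planted_term)
    return obo_text, direct, study, truth


def gen_promoters(
    n_genes: int,
    length: int = 3000,
    plant_spec: Mapping[str, Sequence[tuple[int, str]]] | None = None,
    gc: float = 0.5,
    forbid_background_hits: bool = False,
    pattern: str = P1BS,
    seed: int = 0,
    max_resample: int = 10_000,
    gene_ids: Sequence[str] | None = None,
) -> tuple[list[PromoterRecord], SyntheticTruth]:
    """Fixed-length upstream sequences with motifs planted at known distances.

    ``plant_spec`` maps gene ids to ``(upstream_distance, concrete k-mer)``
    pairs; each k-mer is written so its nearest base sits exactly at the
    stated distance from the translation start.  Planted k-mers must conform
    to ``pattern`` (set ``pattern=None`` to skip the check).  With
    ``forbid_background_hits`` the background is rejection-sampled until the
    only pattern occurrences are the planted ones, so a scan reproduces the
    planted truth exactly.  Genes absent from ``plant_spec`` get pure
    background sequence.
    """
    if not 0 <= gc <= 1:
        raise ValueError("gc must lie in [0, 1]")
    plant_spec = dict(plant_spec or {})
    compiled = compile_iupac(pattern) if pattern else None
    if gene_ids is not None:
        genes = list(gene_ids)
        if len(genes) != len(set(genes)):
            raise ValueError("gene_ids contains duplicates")
    elif plant_spec and n_genes == len(plant_spec):
        genes = sorted(plant_spec)
    else:
        genes = _gene_ids(n_genes, prefix="PG")
    unknown = set(plant_spec) - set(genes)
    if unknown:
        raise ValueError(f"plant_spec genes outside the generated set: {sorted(unknown)}")

    rng = _rng(seed, "promoters")
    bases = np.array(list("ACGT"))
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    records = []
    truth_motifs: dict[str, list[tuple[int, str]]] = {}
    for gene in genes:
        plants = sorted(plant_spec.get(gene, ()), key=lambda p: p[0])
        occupied: set[int] = set()
        placements = []  # (string start 0-based, kmer)
        for d, kmer in plants:
            m = len(kmer)
            if compiled is not None and not matches(kmer.upper(), compiled):
                raise ValueError(
                    f"{gene}: planted {kmer!r} does not conform to {pattern}")
            if not 1 <= d <= length - m + 1:
                raise ValueError(f"{gene}: distance {d} outside [1, {length - m + 1}]")
            s0 = length - d - m + 1  # 0-based string start
            span = set(range(s0, s0 + m))
            if span & occupied:
                raise ValueError(f"{gene}: planted motifs overlap at distance {d}")
            occupied |= span
            placements.append((s0, kmer.upper()))
        seq = rng.choice(bases, size=length, p=probs)
        for s0, kmer in placements:
            seq[s0:s0 + len(kmer)] = list(kmer)
        if forbid_background_hits and compiled is not None:
            planted_starts = {s0 for s0, _ in placements}
            mlen = len(compiled)
            for _ in range(max_resample):
                s = "".join(seq)
                offending = [
                    i for i in range(length - mlen + 1)
                    if i not in planted_starts and matches(s[i:i + mlen], compiled)
                ]
                if not offending:
                    break
                for i in offending:
                    free = [j for j in range(i, i + mlen) if j not in occupied]
                    # a planted-only window can't match unless background leaks in
                    if not free:
                        raise RuntimeError("planted motifs themselves recreate the pattern")
                    seq[free] = rng.choice(bases, size=len(free), p=probs)
            else:
                raise RuntimeError("could not purge background hits")
        records.append(PromoterRecord(gene, "".join(seq), length))
        if placements:
            truth_motifs[gene] = [(d, k.upper()) for d, k in plants]
    return records, SyntheticTruth(planted_motifs=truth_motifs)


# ---------------------------------------------------------------------------
# IO

def write_abundance_tsv(
    treatment: pd.DataFrame, control: pd.DataFrame, path
) -> None:
    """Combined abundance TSV: gene, ctrl_1..ctrl_n, trt_1..trt_n."""
    out = pd.concat(
        [control.rename(columns=lambda c: c.replace("rep", "ctrl")),
         treatment.rename(columns=lambda c: c.replace("rep", "trt"))],
        axis=1,
    )
    out.to_csv(path, sep="\t")


def read_abundance_tsv(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inverse of :func:`write_abundance_tsv` -> (treatment, control)."""
    df = pd.read_csv(path, sep="\t", index_col="gene")
    trt = df[[c for c in df.columns if c.startswith("trt_")]]
    ctrl = df[[c for c in df.columns if c.startswith("ctrl_")]]
    return trt, ctrl


def write_promoter_fasta(records: Sequence[PromoterRecord], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    seqs = [
        SeqRecord(Seq(r.sequence), id=r.gene,
                  description=f"upstream_length={r.upstream_length}")
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")
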