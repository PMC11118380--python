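"""Synthetic inputs with planted ground truth.

Expression matrices carry planted (LPS, pH, INT) log2 components with
multiplicative (log-additive Gaussian) noise; proteomes carry planted
histidine clusters in proline/glutamine-rich disordered context plus a
sidecar of per-residue disorder scores.  Everything is deterministic given a
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .deconvolution import CONDITIONS, ExpressionMatrix

# planted regulatory-logic labels -> (sign_LPS, sign_pH, sign_INT)
TRUTH_LABELS = {
    "null": (0, 0, 0),
    "pH_insensitive_up": (1, 0, 0),
    "pH_insensitive_down": (-1, 0, 0),
    "pH_only_up": (0, 1, 0),
    "pH_only_down": (0, -1, 0),
    "pH_antagonistic": (1, 0, -1),
    "pH_antagonistic_down": (-1, 0, 1),
    "pH_synergistic": (1, 0, 1),
    "pH_synergistic_down": (-1, 0, -1),
}

#: category each planted label should land in after classification
LABEL_TO_CATEGORY = {
    "null": "unassigned",
    "pH_insensitive_up": "pH_insensitive",
    "pH_insensitive_down": "pH_insensitive",
    "pH_only_up": "pH_only",
    "pH_only_down": "pH_only",
    "pH_antagonistic": "pH_antagonistic",
    "pH_antagonistic_down": "pH_antagonistic",
    "pH_synergistic": "pH_synergistic",
    "pH_synergistic_down": "pH_synergistic",
}

DEFAULT_GROUP_MIX = {
    "null": 0.40,
    "pH_insensitive_up": 0.15,
    "pH_insensitive_down": 0.10,
    "pH_only_up": 0.05,
    "pH_only_down": 0.05,
    "pH_antagonistic": 0.10,
    "pH_antagonistic_down": 0.05,
    "pH_synergistic": 0.05,
    "pH_synergistic_down": 0.05,
}


@dataclass
class ExpressionTruth:
    gene_id: str
    beta_true: tuple  # (LPS, pH, INT) in log2-fold units
    baseline: float  # log2 of mean normalized count at pH 7.4 unstimulated
    group_true: str


def _condition_log2_mean(baseline: float, beta: Sequence[float]) -> np.ndarray:
    """Per-condition expected log2 count, CONDITIONS order."""
    lps, ph, int_ = beta
    return np.array([
        baseline,                    # pH74
        baseline + lps,              # pH74_LPS
        baseline + ph,               # pH65
        baseline + lps + ph + int_,  # pH65_LPS
    ])


def simulate_expression(
    n_genes: int = 5000,
    group_mix: Mapping[str, float] | None = None,
    effect_scale: float = 2.0,
    noise_sd: float = 0.25,
    n_replicate_sets: int = 2,
    baseline_range: tuple[float, float] = (3.0, 12.0),
    seed: int = 0,
) -> tuple[ExpressionMatrix, list[ExpressionTruth]]:
    """Simulate a 4-condition count matrix with planted components.

    Per-gene log2 counts are ``baseline`` plus the planted component
    contributions (LPS added to both stimulated conditions, pH to both acidic
    conditions, INT only to the acidic stimulated condition) plus independent
    Gaussian noise of sd ``noise_sd``; counts are exponentiated, rounded to
    the nearest integer and floored at zero.
    """
    if not isinstance(seed, (int, np.integer)) or isinstance(seed, bool):
        raise TypeError("seed must be an integer")
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if effect_scale <= 0:
        raise ValueError("effect_scale must be > 0")
    mix = dict(group_mix) if group_mix is not None else dict(DEFAULT_GROUP_MIX)
    if not mix:
        raise ValueError("group_mix must be non-empty")
    unknown = set(mix) - set(TRUTH_LABELS)
    if unknown:
        raise ValueError(f"unknown planted labels: {sorted(unknown)}")
    probs = np.array(list(mix.values()), dtype=float)
    if abs(probs.sum() - 1.0) > 1e-8:
        raise ValueError("group_mix must sum to 1")

    rng = np.random.default_rng(seed)
    labels = rng.choice(list(mix.keys()), size=n_genes, p=probs)
    baselines = rng.uniform(*baseline_range, size=n_genes)

    sample_rows = []
    for rep in range(1, n_replicate_sets + 1):
        for cond in CONDITIONS:
            sample_rows.append({
                "sample_id": f"{cond}_r{rep}",
                "condition": cond,
                "replicate_set": rep,
            })
    design = pd.DataFrame(sample_rows)

    truths = []
    log2_means = np.empty((n_genes, 4))
    for g in range(n_genes):
        signs = TRUTH_LABELS[labels[g]]
        beta = tuple(s * effect_scale for s in signs)
        log2_means[g] = _condition_log2_mean(baselines[g], beta)
        truths.append(ExpressionTruth(
            gene_id=f"gene{g + 1:05d}",
            beta_true=beta,
            baseline=float(baselines[g]),
            group_true=str(labels[g]),
        ))

    counts = {}
    for row in sample_rows:
        j = CONDITIONS.index(row["condition"])
        noise = rng.normal(0.0, noise_sd, size=n_genes) if noise_sd > 0 else 0.0
        vals = np.maximum(np.rint(2.0 ** (log2_means[:, j] + noise)), 0.0)
        counts[row["sample_id"]] = vals
    counts_df = pd.DataFrame(counts, index=[t.gene_id for t in truths])
    return ExpressionMatrix(counts_df, design), truths


def truth_table(truths: Sequence[ExpressionTruth]) -> pd.DataFrame:
    return pd.DataFrame({
        "gene_id": [t.gene_id for t in truths],
        "beta_LPS": [t.beta_true[0] for t in truths],
        "beta_pH": [t.beta_true[1] for t in truths],
        "beta_INT": [t.beta_true[2] for t in truths],
        "baseline": [t.baseline for t in truths],
        "group_true": [t.group_true for t in truths],
        "category_true": [LABEL_TO_CATEGORY[t.group_true] for t in truths],
    })


# ---------------------------------------------------------------------------
# Proteome simulation
# ---------------------------------------------------------------------------

MOTIF_CLASSES = ("his_cluster_in_PQ", "his_cluster_ordered", "isolated_his", "no_his")


@dataclass
class MotifSpec:
    """Description of a planted motif class.

    ``his_cluster_in_PQ``: a run of ``n_his`` histidines centred in a
    ``pq_len``-residue P/Q-rich block, with high sidecar disorder scores over
    the block and its flanks.  ``his_cluster_ordered``: same sequence motif
    but low disorder scores everywhere.  ``isolated_his``: exactly one
    histidine in the whole protein.  ``no_his``: histidine-free background.
    """

    motif_class: str
    count: int = 1
    n_his: int = 6
    pq_len: int = 40

    def __post_init__(self) -> None:
        if self.motif_class not in MOTIF_CLASSES:
            raise ValueError(f"unknown motif class {self.motif_class!r}")


@dataclass
class ProteomeTruth:
    protein_id: str
    motif_class: str
    planted_regions: list  # [(start, end)] 1-based inclusive
    disorder_scores: np.ndarray


DEFAULT_BACKGROUND = {aa: 0.05 for aa in "ACDEFGHIKLMNPQRSTVWY"}

HIGH_DISORDER = 0.8
LOW_DISORDER = 0.1


def _draw_background(rng, length: int, freqs: Mapping[str, float], drop_his: bool) -> list:
    aas = [a for a in freqs if not (drop_his and a == "H")]
    p = np.array([freqs[a] for a in aas], dtype=float)
    p /= p.sum()
    return list(rng.choice(aas, size=length, p=p))


def simulate_proteome(
    n_proteins: int = 100,
    length_range: tuple[int, int] = (200, 600),
    background_freqs: Mapping[str, float] | None = None,
    motif_specs: Sequence[MotifSpec] | None = None,
    flank: int = 50,
    seed: int = 0,
) -> tuple[list, list[ProteomeTruth], pd.DataFrame]:
    """Simulate protein sequences with planted motifs and a disorder sidecar.

    ``motif_specs`` assigns each motif class a number of proteins; proteins
    beyond the spec total are plain background.  Returns
    (:class:`phdecon.io.ProteinRecord` list, truth list, sidecar DataFrame
    with columns protein_id / position / score).
    """
    from .io import ProteinRecord  # deferred to avoid a cycle

    if not isinstance(seed, (int, np.integer)) or isinstance(seed, bool):
        raise TypeError("seed must be an integer")
    freqs = dict(background_freqs) if background_freqs else dict(DEFAULT_BACKGROUND)
    total = sum(freqs.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError("background_freqs must sum to 1")
    if motif_specs is None:
        motif_specs = [
            MotifSpec("his_cluster_in_PQ", count=max(1, n_proteins // 10)),
            MotifSpec("his_cluster_ordered", count=max(1, n_proteins // 10)),
            MotifSpec("no_his", count=max(1, n_proteins // 10)),
        ]
    assignments = []
    for spec in motif_specs:
        assignments.extend([spec] * spec.count)
    if len(assignments) > n_proteins:
        raise ValueError("motif_specs assign more proteins than n_proteins")
    assignments.extend([None] * (n_proteins - len(assignments)))

    rng = np.random.default_rng(seed)
    records, truths, sidecar_rows = [], [], []
    for i, spec in enumerate(assignments):
        pid = f"prot{i + 1:04d}"
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        klass = spec.motif_class if spec else "background"
        if spec and spec.motif_class != "no_his":
            min_len = 2 * flank + (spec.pq_len if "cluster" in spec.motif_class else 1)
            if length < min_len:
                raise ValueError(
                    f"protein length {length} too short for motif "
                    f"{spec.motif_class!r} (needs >= {min_len})"
                )
        drop_his = klass in ("no_his", "isolated_his")
        seq = _draw_background(rng, length, freqs, drop_his)
        scores = np.full(length, LOW_DISORDER)
        regions = []

        if klass in ("his_cluster_in_PQ", "his_cluster_ordered"):
            block = spec.pq_len
            start = int(rng.integers(flank, length - flank - block + 1))  # 0-based
            pq = rng.choice(["P", "Q"], size=block)
            seq[start : start + block] = list(pq)
            run_start = start + (block - spec.n_his) // 2
            seq[run_start : run_start + spec.n_his] = ["H"] * spec.n_his
            regions.append((start + 1, start + block))
            if klass == "his_cluster_in_PQ":
                lo = max(0, start - flank)
                hi = min(length, start + block + flank)
                scores[lo:hi] = HIGH_DISORDER
        elif klass == "isolated_his":
            pos = int(rng.integers(0, length))
            seq[pos] = "H"
            regions.append((pos + 1, pos + 1))

        if klass == "no_his":
            assert "H" not in seq
        sequence = "".join(seq)
        records.append(ProteinRecord(
            accession=pid,
            description=f"synthetic {klass}",
            sequence=sequence,
        ))
        truths.append(ProteomeTruth(
            protein_id=pid,
            motif_class=klass,
            planted_regions=regions,
            disorder_scores=scores,
        ))
        sidecar_rows.append(pd.DataFrame({
            "protein_id": pid,
            "position": np.arange(1, length + 1),
            "score": scores,
        }))
    sidecar = pd.concat(sidecar_rows, ignore_index=True)
    return records, truths, sidecar


# ---------------------------------------------------------------------------
# Packaged toy fixtures
# ---------------------------------------------------------------------------


def fixture_tables():
    """Deterministic toy fixtures: a 12-gene expression table and a
    5-protein FASTA-ready record set with disorder sidecar.

    The proteome includes one BRD4-like protein (6-H run inside a PQ-rich
    disordered block), one ordered histidine cluster, one histidine-free
    protein, one isolated-histidine protein and one background protein.
    """
    labels = [
        "null", "null", "null",
        "pH_insensitive_up", "pH_insensitive_up", "pH_insensitive_down",
        "pH_only_up", "pH_only_down",
        "pH_antagonistic", "pH_antagonistic",
        "pH_synergistic", "pH_synergistic_down",
    ]
    mix = {lab: labels.count(lab) / len(labels) for lab in set(labels)}
    matrix, truths = simulate_expression(
        n_genes=12,
        group_mix=mix,
        effect_scale=2.0,
        noise_sd=0.1,
        n_replicate_sets=2,
        baseline_range=(8.0, 12.0),
        seed=20240510,
    )
    records, prot_truths, sidecar = simulate_proteome(
        n_proteins=5,
        length_range=(300, 400),
        motif_specs=[
            MotifSpec("his_cluster_in_PQ", count=1),
            MotifSpec("his_cluster_ordered", count=1),
            MotifSpec("no_his", count=1),
            MotifSpec("isolated_his", count=1),
        ],
        seed=20240510,
    )
    return matrix, truths, records, prot_truths, sidecar
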