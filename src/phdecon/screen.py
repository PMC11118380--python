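"""Proteome-wide screen for pH-sensitive histidine-enriched disordered regions.

The screen smooths a histidine indicator with a truncated unit-peak Gaussian
kernel (FWHM 5, spanning ~20 residues) to obtain a per-residue delta-charge
profile in histidine-equivalents, calls peaks above a strict threshold,
extends each peak by 50 residues on both sides, gates on per-side disorder
scores and ranks by proline/glutamine enrichment.  Descriptive residue
arithmetic (histidine runs, H->A mutagenesis, net charge, composition
enrichment) supports candidate characterization.

All residue coordinates are 1-based inclusive.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: FWHM = 2 * sqrt(2 ln 2) * sigma
FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


class ScreenError(ValueError):
    pass


@dataclass(frozen=True)
class SmoothingKernel:
    """Truncated symmetric Gaussian with unit peak amplitude.

    ``weights[k]`` covers integer offsets ``-half .. +half`` where
    ``half = span // 2``; ``weights`` is indexed so that the centre tap
    (offset 0, weight exactly 1) sits at position ``half``.
    """

    fwhm: float
    span: int
    sigma: float
    weights: np.ndarray

    @property
    def half(self) -> int:
        return self.span // 2


def make_kernel(fwhm: float = 5.0, span: int = 20) -> SmoothingKernel:
    """Build the smoothing kernel; ``sigma = fwhm / (2 sqrt(2 ln 2))``."""
    if fwhm <= 0:
        raise ScreenError("fwhm must be positive")
    if span < 1:
        raise ScreenError("span must be >= 1")
    sigma = fwhm / FWHM_TO_SIGMA
    half = span // 2
    offsets = np.arange(-half, half + 1)
    weights = np.exp(-(offsets.astype(float) ** 2) / (2.0 * sigma**2))
    return SmoothingKernel(fwhm=fwhm, span=span, sigma=sigma, weights=weights)


def residue_indicator(sequence: str, residue_set: Iterable[str]) -> np.ndarray:
    """Binary vector: 1 where the residue belongs to ``residue_set``."""
    residues = set(residue_set)
    if not residues:
        raise ScreenError("residue_set must be non-empty")
    return np.fromiter(
        (1.0 if aa in residues else 0.0 for aa in sequence),
        dtype=float,
        count=len(sequence),
    )


def smooth(indicator: np.ndarray, kernel: SmoothingKernel) -> np.ndarray:
    """Convolve with the truncated kernel, zero-padded at the boundaries."""
    indicator = np.asarray(indicator, dtype=float)
    if indicator.size == 0:
        return indicator.copy()
    # np.convolve "same" centre-aligns the odd-length symmetric kernel
    return np.convolve(indicator, kernel.weights, mode="same")


def delta_charge_profile(
    sequence: str,
    kernel: SmoothingKernel | None = None,
    his_weight: float = 1.0,
) -> np.ndarray:
    """Smoothed histidine profile in histidine-equivalent charge units.

    With the default ``his_weight`` of 1 each histidine counts as one unit of
    protonatable charge; a fractional weight (e.g. the protonation difference
    between two pH values) rescales the profile linearly.
    """
    kernel = kernel or make_kernel()
    return smooth(residue_indicator(sequence, {"H"}) * his_weight, kernel)


def find_peaks(
    profile: np.ndarray,
    charge_threshold: float = 1.0,
    min_peak_separation: int = 20,
) -> list[int]:
    """Local maxima strictly above ``charge_threshold``, 1-based positions.

    Plateau positions count as local maxima.  Peaks closer than
    ``min_peak_separation`` are merged keeping the larger value (ties broken
    toward the smaller index).  Output is sorted by position.
    """
    if charge_threshold <= 0:
        raise ScreenError("charge_threshold must be positive")
    prof = np.asarray(profile, dtype=float)
    n = prof.size
    candidates = []
    for i in range(n):
        if prof[i] <= charge_threshold:
            continue
        left = prof[i - 1] if i > 0 else -np.inf
        right = prof[i + 1] if i < n - 1 else -np.inf
        if prof[i] >= left and prof[i] >= right:
            candidates.append(i)
    merged: list[int] = []
    for i in candidates:
        if merged and i - merged[-1] < min_peak_separation:
            if prof[i] > prof[merged[-1]]:
                merged[-1] = i
            # ties keep the earlier (smaller) index
        else:
            merged.append(i)
    return [i + 1 for i in merged]


def extend_region(peak_pos: int, length: int, flank: int = 50) -> tuple[int, int]:
    """[max(1, peak - flank), min(length, peak + flank)], 1-based inclusive."""
    if not 1 <= peak_pos <= length:
        raise ScreenError(f"peak position {peak_pos} outside sequence 1..{length}")
    return max(1, peak_pos - flank), min(length, peak_pos + flank)


def assess_disorder(
    scores: np.ndarray,
    region: tuple[int, int],
    peak_pos: int,
    threshold: float = 0.3,
    aggregate: str = "mean",
) -> tuple[float, float, bool]:
    """Per-side disorder summary over the extended region.

    ``disorder_n`` aggregates predictor scores over ``[start, peak-1]`` and
    ``disorder_c`` over ``[peak+1, end]`` (empty side -> 0).  The region is
    disordered when either side exceeds ``threshold``.
    """
    scores = np.asarray(scores, dtype=float)
    start, end = region
    agg = np.mean if aggregate == "mean" else np.max
    n_side = scores[start - 1 : peak_pos - 1]
    c_side = scores[peak_pos:end]
    disorder_n = float(agg(n_side)) if n_side.size else 0.0
    disorder_c = float(agg(c_side)) if c_side.size else 0.0
    return disorder_n, disorder_c, bool(
        disorder_n > threshold or disorder_c > threshold
    )


def pq_score(
    sequence: str,
    peak_pos: int,
    region: tuple[int, int],
    kernel: SmoothingKernel | None = None,
) -> float:
    """Proline/glutamine enrichment around a delta-charge peak.

    The P and Q indicators are smoothed separately with the same kernel and
    summed; the score is the larger of the two side maxima (N side
    ``[start, peak-1]``, C side ``[peak+1, end]``) within the region.
    """
    kernel = kernel or make_kernel()
    start, end = region
    density = smooth(residue_indicator(sequence, {"P"}), kernel) + smooth(
        residue_indicator(sequence, {"Q"}), kernel
    )
    n_side = density[start - 1 : peak_pos - 1]
    c_side = density[peak_pos:end]
    n_max = float(n_side.max()) if n_side.size else 0.0
    c_max = float(c_side.max()) if c_side.size else 0.0
    return max(n_max, c_max)


# ---------------------------------------------------------------------------
# Residue arithmetic
# ---------------------------------------------------------------------------


def his_protonation_fraction(pH: float, pKa: float = 6.0) -> float:
    """Henderson-Hasselbalch protonated fraction of a histidine side chain."""
    return 1.0 / (1.0 + 10.0 ** (pH - pKa))


def his_protonation_delta(pH_a: float, pH_b: float, pKa: float = 6.0) -> float:
    """Gain in protonated fraction when moving from ``pH_a`` to ``pH_b``."""
    return his_protonation_fraction(pH_b, pKa) - his_protonation_fraction(pH_a, pKa)


def net_charge(
    sequence: str,
    interval: tuple[int, int] | None = None,
    mode: str = "neutral",
    pH: float = 6.5,
    pKa: float = 6.0,
) -> float:
    """Integer-model net charge: +1 per K/R, -1 per D/E.

    Histidine contributes 0 in ``"neutral"`` mode (pH 7.4 approximation) or
    its protonated fraction at ``pH`` in ``"acidic"`` mode.  Terminal charges
    and pKa shifts are deliberately ignored.
    """
    seg = _slice(sequence, interval)
    charge = sum(1 for aa in seg if aa in "KR") - sum(1 for aa in seg if aa in "DE")
    if mode == "acidic":
        charge += seg.count("H") * his_protonation_fraction(pH, pKa)
    return float(charge)


def longest_his_run(sequence: str, interval: tuple[int, int] | None = None) -> int:
    """Length of the longest run of consecutive H within the interval."""
    seg = _slice(sequence, interval)
    best = run = 0
    for aa in seg:
        run = run + 1 if aa == "H" else 0
        best = max(best, run)
    return best


def mutate_his_to_ala(
    sequence: str, interval: tuple[int, int] | None = None
) -> tuple[str, int]:
    """Replace every histidine inside the interval with alanine."""
    start, end = interval or (1, len(sequence))
    _check_interval(sequence, (start, end))
    seg = sequence[start - 1 : end]
    n = seg.count("H")
    mutated = sequence[: start - 1] + seg.replace("H", "A") + sequence[end:]
    return mutated, n


def count_residues(
    sequence: str, residues: Iterable[str], interval: tuple[int, int] | None = None
) -> int:
    """Number of residues within the interval belonging to ``residues``."""
    seg = _slice(sequence, interval)
    residues = set(residues)
    return sum(1 for aa in seg if aa in residues)


def composition_enrichment(
    target: str,
    background: Sequence[str],
    epsilon: float = 1e-4,
) -> pd.Series:
    """Per-amino-acid log2 frequency ratio of target vs pooled background."""
    if not target:
        raise ScreenError("target sequence is empty")
    if not background:
        raise ScreenError("background must be non-empty")
    pool = "".join(background)
    t_counts = Counter(target)
    b_counts = Counter(pool)
    out = {}
    for aa in AMINO_ACIDS:
        ft = t_counts.get(aa, 0) / len(target)
        fb = b_counts.get(aa, 0) / len(pool)
        out[aa] = math.log2((ft + epsilon) / (fb + epsilon))
    return pd.Series(out, name="log2_enrichment")


def _slice(sequence: str, interval: tuple[int, int] | None) -> str:
    if interval is None:
        return sequence
    _check_interval(sequence, interval)
    return sequence[interval[0] - 1 : interval[1]]


def _check_interval(sequence: str, interval: tuple[int, int]) -> None:
    start, end = interval
    if not (1 <= start <= end <= len(sequence)):
        raise ScreenError(
            f"interval {interval} outside sequence of length {len(sequence)}"
        )


# ---------------------------------------------------------------------------
# Proteome screen
# ---------------------------------------------------------------------------


@dataclass
class ScreenConfig:
    fwhm: float = 5.0
    span: int = 20
    charge_threshold: float = 1.0
    flank: int = 50
    disorder_threshold: float = 0.3
    min_peak_separation: int = 20
    disorder_aggregate: str = "mean"
    apply_disorder_gate: bool = True
    expression_min_mean: float = 5.0
    his_weight: float = 1.0

    def kernel(self) -> SmoothingKernel:
        return make_kernel(self.fwhm, self.span)


CANDIDATE_COLUMNS = [
    "accession", "peak_pos", "delta_charge", "start", "end",
    "disorder_n", "disorder_c", "disordered", "pq_score",
    "expressed", "net_charge",
]


DisorderSource = Mapping[str, np.ndarray] | Callable[[str, str], np.ndarray]


def _disorder_scores(source, accession: str, sequence: str):
    if source is None:
        return None
    if callable(source):
        return np.asarray(source(accession, sequence), dtype=float)
    return np.asarray(source[accession], dtype=float)


def screen_proteome(
    records: Sequence,
    config: ScreenConfig | None = None,
    disorder: DisorderSource | None = None,
    expression: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Run the full screen over protein records.

    Parameters
    ----------
    records:
        Objects with ``accession`` and ``sequence`` attributes (see
        :class:`phdecon.io.ProteinRecord`).
    disorder:
        Per-residue score source: a mapping ``accession -> scores`` or a
        callable ``(accession, sequence) -> scores``.  Missing scores mark a
        region's disorder status as unknown.
    expression:
        Optional ``identifier -> mean normalized count`` mapping (matched
        case-insensitively on accession); regions of unmatched proteins get
        ``expressed = "unknown"``.

    Returns the candidate table sorted by (delta_charge desc, accession,
    peak position) and a filter-funnel summary.
    """
    cfg = config or ScreenConfig()
    kernel = cfg.kernel()
    expr_lut = (
        {str(k).upper(): float(v) for k, v in expression.items()}
        if expression is not None
        else None
    )
    rows = []
    n_peaks = n_disordered = n_unknown = 0
    for rec in records:
        seq = rec.sequence
        if not seq:
            logger.warning("screen: skipping empty record %r", rec.accession)
            continue
        profile = delta_charge_profile(seq, kernel, cfg.his_weight)
        peaks = find_peaks(profile, cfg.charge_threshold, cfg.min_peak_separation)
        n_peaks += len(peaks)
        scores = None
        scores_err = None
        if disorder is not None:
            try:
                scores = _disorder_scores(disorder, rec.accession, seq)
                if scores is not None and len(scores) != len(seq):
                    raise ValueError("disorder score length mismatch")
            except Exception as exc:  # predictor failure -> unknown
                scores_err = exc
                scores = None
        if expr_lut is None:
            expressed = "unknown"
        else:
            mean_count = expr_lut.get(rec.accession.upper())
            expressed = (
                "unknown" if mean_count is None
                else bool(mean_count > cfg.expression_min_mean)
            )
        for peak in peaks:
            region = extend_region(peak, len(seq), cfg.flank)
            if scores is None:
                if scores_err is not None:
                    logger.warning(
                        "screen: disorder unavailable for %s: %s",
                        rec.accession, scores_err,
                    )
                disorder_n = disorder_c = float("nan")
                disordered = "unknown"
                n_unknown += 1
            else:
                disorder_n, disorder_c, flag = assess_disorder(
                    scores, region, peak, cfg.disorder_threshold,
                    cfg.disorder_aggregate,
                )
                disordered = bool(flag)
                n_disordered += int(flag)
            rows.append({
                "accession": rec.accession,
                "peak_pos": peak,
                "delta_charge": float(profile[peak - 1]),
                "start": region[0],
                "end": region[1],
                "disorder_n": disorder_n,
                "disorder_c": disorder_c,
                "disordered": disordered,
                "pq_score": pq_score(seq, peak, region, kernel),
                "expressed": expressed,
                "net_charge": net_charge(seq, region),
            })
    table = pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)
    if cfg.apply_disorder_gate and disorder is not None and len(table):
        table = table[table["disordered"] == True]  # noqa: E712 (column mixes bool/"unknown")
    if len(table):
        table = table.sort_values(
            ["delta_charge", "accession", "peak_pos"],
            ascending=[False, True, True],
            kind="mergesort",
        ).reset_index(drop=True)
    summary = {
        "n_proteins": len(records),
        "n_peak_regions": n_peaks,
        "n_disordered_regions": n_disordered,
        "n_unknown_disorder": n_unknown,
        "n_retained_regions": int(len(table)),
        "config": vars(cfg),
    }
    logger.info(
        "screen: %d proteins, %d peak regions, %d disordered",
        len(records), n_peaks, n_disordered,
    )
    return table, summary
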