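"""Derived statistics and quality-control metrics.

Covers the immobile-element audit (sensitivity and artefact counts), the
log-log regression of artefact counts against element abundance (slope
near 1 is the signature of random genome sampling rather than genuine
mobilisation), the "hovering" profile of artefact calls around germline
element copies, FPKM element quantification, depth normalisation, the
pooled-sample detection-odds arithmetic, and a delta-delta-Ct fold-change
utility for qPCR expression tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_io import Interval
from .insertion_caller import InsertionCall
from .micromap import AlignedPair


@dataclass
class RegressionResult:
    slope: float
    stderr: float
    intercept: float
    r2: float
    n: int


@dataclass
class IgeMetrics:
    """Per-sample immobile-element audit.

    Recovered germline junctions measure sensitivity; additional IGE
    calls are library artefacts, a direct proxy for the false-discovery
    rate of insertion calling on this sample.
    """

    sample_id: str
    n_expected: int
    n_recovered: int
    n_artefact: int

    @property
    def sensitivity(self) -> float:
        return self.n_recovered / self.n_expected if self.n_expected else float("nan")


def ige_metrics(
    calls: list[InsertionCall],
    expected: list[Interval],
    pad: int = 250,
    sample_id: str = "",
) -> IgeMetrics:
    """Score IGE calls against the expected excision-point junctions.

    An expected junction is recovered when a call for the same IGE
    overlaps its window extended by ``pad``; calls matching no expected
    junction count as artefacts.
    """
    recovered = 0
    matched: set[int] = set()
    for ej in expected:
        hit = False
        for idx, call in enumerate(calls):
            if (
                call.element == ej.name
                and call.chrom == ej.chrom
                and call.start < ej.end + pad
                and ej.start - pad < call.end
            ):
                matched.add(idx)
                hit = True
        if hit:
            recovered += 1
    return IgeMetrics(
        sample_id=sample_id,
        n_expected=len(expected),
        n_recovered=recovered,
        n_artefact=len(calls) - len(matched),
    )


def loglog_abundance_regression(
    abundance: dict[str, float], counts: dict[str, float]
) -> RegressionResult:
    """OLS on log10 axes of per-element call counts vs normalised
    genomic abundance.

    Elements with a zero on either axis are excluded (no pseudocounts);
    fewer than 3 usable points is a hard error. Rescaling either axis by
    a positive constant leaves the slope unchanged.
    """
    xs, ys = [], []
    for name in abundance:
        x = abundance[name]
        y = counts.get(name, 0)
        if x > 0 and y > 0:
            xs.append(np.log10(x))
            ys.append(np.log10(y))
    if len(xs) < 3:
        raise ValueError(f"only {len(xs)} usable points for the regression")
    fit = sps.linregress(xs, ys)
    return RegressionResult(
        slope=float(fit.slope),
        stderr=float(fit.stderr),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        n=len(xs),
    )


def hovering_profile(
    calls: list[InsertionCall], germline_loci: list[Interval]
) -> dict:
    """Signed distance of each call to the nearest germline copy of the
    same element (call midpoint to nearest locus edge; positive =
    downstream; 0 inside). Calls whose element has no germline copy go
    to an unassigned bucket."""
    by_element: dict[str, list[Interval]] = {}
    for iv in germline_loci:
        by_element.setdefault(iv.name, []).append(iv)
    distances: list[tuple[str, str, int]] = []
    unassigned: list[InsertionCall] = []
    for call in calls:
        loci = [iv for iv in by_element.get(call.element, []) if iv.chrom == call.chrom]
        if not loci:
            unassigned.append(call)
            continue
        mid = call.midpoint
        best = None
        for iv in loci:
            if mid < iv.start:
                d = mid - iv.start
            elif mid >= iv.end:
                d = mid - (iv.end - 1)
            else:
                d = 0
            if best is None or abs(d) < abs(best):
                best = d
        distances.append((call.element, call.chrom, best))
    abs_d = np.array([abs(d) for _, _, d in distances]) if distances else np.array([])
    return {
        "distances": distances,
        "n_assigned": len(distances),
        "n_unassigned": len(unassigned),
        "median_abs_nt": float(np.median(abs_d)) if len(abs_d) else None,
        "frac_within_10kb": float(np.mean(abs_d <= 10_000)) if len(abs_d) else None,
    }


def element_fpkm(
    pairs: list[AlignedPair],
    te_intervals: list[Interval],
    te_chrom: str = "TE",
) -> dict[str, float]:
    """Fragments per kilobase of element sequence per million mapped
    fragments; a fragment is counted once, by its leftmost unique mate."""
    total_mapped = 0
    starts: list[tuple[str, int]] = []
    for p in pairs:
        mates = [m for m in (p.mate1, p.mate2) if m.unique]
        if not mates:
            continue
        total_mapped += 1
        left = min(mates, key=lambda m: (m.chrom, m.pos))
        if left.chrom == te_chrom:
            starts.append((left.chrom, left.pos))
    if total_mapped == 0:
        raise ValueError("no mapped fragments")
    out = {}
    for iv in te_intervals:
        if iv.length == 0:
            raise ValueError(f"zero-length element {iv.name!r}")
        n = sum(1 for c, pos in starts if c == iv.chrom and iv.start <= pos < iv.end)
        out[iv.name] = n / (iv.length / 1e3) / (total_mapped / 1e6)
    return out


def normalize_to_depth(
    count: float, sample_coverage: float, target_coverage: float
) -> tuple[float, str, bool]:
    """Linear depth normalisation of a call count.

    Returns (scaled count, method, warned). Upscaling (target above the
    sample coverage) is flagged — subsampling cannot manufacture reads,
    so only the linear estimate is available there.
    """
    if sample_coverage <= 0 or target_coverage <= 0:
        raise ValueError("coverages must be positive")
    warned = target_coverage > sample_coverage
    return count * target_coverage / sample_coverage, "linear", warned


def subsample_pairs(pairs: list, fraction: float, seed: int) -> list:
    """Seeded, deterministic read-pair subsampling (the preferred route
    to a target depth when the reads are in hand)."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    keep = rng.random(len(pairs)) < fraction
    return [p for p, k in zip(pairs, keep) if k]


def pooling_dilution(
    n_flies: int, cells_per_fly: int, ploidy: int, depth: float
) -> tuple[int, float]:
    """Detection odds for pooled-sample sequencing.

    Pooling ``n_flies`` animals with ``cells_per_fly`` target cells at
    the given ploidy yields ``copies`` of every locus; at a sequencing
    depth of ``depth`` only 1 in ``copies / depth`` single-locus events
    is expected to be observed.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if min(n_flies, cells_per_fly, ploidy) <= 0:
        raise ValueError("counts must be positive")
    copies = n_flies * cells_per_fly * ploidy
    return copies, copies / depth


def ddct_fold_change(
    ct: pd.DataFrame,
    target: str,
    condition_a: str,
    condition_b: str,
    housekeeping: list[str],
) -> dict:
    """Relative expression by the 2^(-ddCt) method.

    ``ct`` needs columns gene/condition/replicate/ct. Per replicate the
    target Ct is normalised to the geometric mean Ct of the housekeeping
    genes; ddCt is the difference of condition means (A - B) and the
    fold change 2^(-ddCt). The combined SEM is the root of the summed
    squared per-condition SEMs, and the bounds are 2^(-(ddCt +/- SEM)).
    Swapping the conditions inverts the fold change exactly.
    """
    if not housekeeping:
        raise ValueError("at least one housekeeping gene is required")
    missing = set(housekeeping) - set(ct["gene"])
    if missing:
        raise ValueError(f"housekeeping gene(s) absent from table: {sorted(missing)}")

    def _dcts(condition: str) -> np.ndarray:
        sub = ct[ct["condition"] == condition]
        if sub.empty:
            raise ValueError(f"condition {condition!r} absent from table")
        out = []
        for _, grp in sub.groupby("replicate"):
            tgt = grp.loc[grp["gene"] == target, "ct"]
            hks = grp[grp["gene"].isin(housekeeping)]["ct"]
            if tgt.empty or hks.empty:
                continue
            out.append(float(tgt.mean()) - float(sps.gmean(hks)))
        if not out:
            raise ValueError(f"no usable replicates for condition {condition!r}")
        return np.asarray(out)

    da, db = _dcts(condition_a), _dcts(condition_b)
    ddct = float(da.mean() - db.mean())
    sem = float(np.sqrt(sps.sem(da) ** 2 + sps.sem(db) ** 2)) if (
        len(da) > 1 and len(db) > 1
    ) else 0.0
    return {
        "ddct": ddct,
        "fold": 2.0 ** (-ddct),
        "lower": 2.0 ** (-(ddct + sem)),
        "upper": 2.0 ** (-(ddct - sem)),
        "sem": sem,
    }


def compare_groups(a, b) -> float:
    """Two-sided Mann-Whitney p-value for group comparisons in reports."""
    return float(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)
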