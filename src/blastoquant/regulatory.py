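"""Motif scanning and the candidate-target filter funnel.

A position-weight-matrix (PWM) model of a transcription-factor binding site
is scored as integer-discretized log-odds against a background nucleotide
model.  The score threshold is calibrated *exactly*: the null score
distribution under the background is computed by dynamic programming over
motif positions, and the threshold is the smallest score whose upper tail
probability is at most ``alpha``.  Sequence scanning reports every window on
either strand at or above the threshold.

The downstream funnel associates hits with genes through fixed-width windows
around transcription start sites (TSS), then requires the hit to be fully
contained in an open-chromatin peak, producing the staged candidate counts
(differentially expressed -> has motif -> motif in open chromatin).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MotifModel",
    "GenomicInterval",
    "MotifHit",
    "ThresholdCalibration",
    "FilterReport",
    "load_pwm",
    "write_pwm",
    "rbpj_consensus_pwm",
    "calibrate_threshold",
    "scan_sequence",
    "window_around_tss",
    "intersect_contained",
    "candidate_filter_report",
    "read_bed",
    "write_bed",
]

_ALPHABET = "ACGT"
#: integer discretization granularity of log-odds scores (grid = 1/SCALE)
SCORE_SCALE = 1000


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"malformed interval {self.chrom}:{self.start}-{self.end}"
            )


class MotifHit(NamedTuple):
    """A super-threshold PWM match, always in forward-strand coordinates."""

    chrom: str
    start: int
    end: int
    strand: str
    score_int: int
    score: float


@dataclass(frozen=True)
class MotifModel:
    """PWM over A/C/G/T with background and pseudocount.

    ``matrix`` holds per-position probabilities, shape (width, 4), columns in
    A, C, G, T order; every row sums to 1.  Scores are log2 odds against
    ``background``.
    """

    matrix: np.ndarray
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    pseudocount: float = 0.0
    name: str = "motif"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] < 1:
            raise ValueError("PWM matrix must have shape (width, 4)")
        if np.any(m < 0):
            raise ValueError("PWM probabilities must be nonnegative")
        if np.max(np.abs(m.sum(axis=1) - 1.0)) > 1e-9:
            raise ValueError("PWM rows must sum to 1")
        bg = np.asarray(self.background, dtype=float)
        if abs(bg.sum() - 1.0) > 1e-9 or np.any(bg <= 0):
            raise ValueError("background must be positive and sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(_ALPHABET[i] for i in self.matrix.argmax(axis=1))

    def log_odds(self) -> np.ndarray:
        """Log2-odds matrix, shape (width, 4); zero-probability cells -inf."""
        bg = np.asarray(self.background)
        with np.errstate(divide="ignore"):
            return np.log2(self.matrix) - np.log2(bg)[None, :]

    def int_scores(self) -> np.ndarray:
        """Integer-discretized log-odds on the 1/SCORE_SCALE grid.

        -inf cells map to a sentinel far below any attainable score so that
        they can never reach a calibrated threshold.
        """
        lo = self.log_odds()
        finite = np.where(np.isfinite(lo), lo, 0.0)
        s = np.rint(finite * SCORE_SCALE).astype(np.int64)
        span = int(np.abs(s).sum()) + 1
        s[~np.isfinite(lo)] = -4 * span
        return s


def _normalize_counts(values: np.ndarray, pseudocount: float) -> np.ndarray:
    totals = values.sum(axis=1, keepdims=True)
    return (values + pseudocount) / (totals + 4.0 * pseudocount)


def load_pwm(
    path,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    pseudocount: float = 1e-3,
    name: str | None = None,
) -> MotifModel:
    """Parse a tab-matrix PWM file (CIS-BP-style table or JASPAR block).

    Count matrices are converted to probabilities as
    ``(count + pc) / (total + 4*pc)``; probability matrices are smoothed as
    ``(p + pc) / (1 + 4*pc)``.
    """
    with open(path) as fh:
        lines = [l.strip() for l in fh if l.strip()]
    if not lines:
        raise ValueError(f"empty PWM file: {path}")
    motif_name = name
    if lines[0].startswith(">"):  # JASPAR block
        motif_name = motif_name or lines[0][1:].split()[0]
        per_base: dict[str, list[float]] = {}
        for l in lines[1:]:
            base = l[0].upper()
            nums = l[l.index("[") + 1:l.rindex("]")] if "[" in l else l[1:]
            per_base[base] = [float(x) for x in nums.split()]
        try:
            cols = np.array([per_base[b] for b in _ALPHABET], dtype=float).T
        except KeyError as exc:
            raise ValueError(f"malformed JASPAR matrix, missing row {exc}")
    else:  # CIS-BP style: header 'Pos A C G T' then one row per position
        rows = []
        for l in lines:
            parts = l.split()
            try:
                vals = [float(x) for x in parts[-4:]]
            except ValueError:
                continue  # header line
            rows.append(vals)
        if not rows:
            raise ValueError(f"no numeric rows in PWM file: {path}")
        cols = np.array(rows, dtype=float)
    if cols.size == 0 or cols.ndim != 2 or cols.shape[1] != 4:
        raise ValueError("malformed PWM matrix")
    row_sums = cols.sum(axis=1)
    if np.all(np.abs(row_sums - 1.0) < 0.05):  # probabilities
        probs = (cols + pseudocount) / (1.0 + 4.0 * pseudocount)
        probs = probs / probs.sum(axis=1, keepdims=True)
    else:  # counts
        probs = _normalize_counts(cols, pseudocount)
    return MotifModel(
        matrix=probs,
        background=tuple(background),
        pseudocount=pseudocount,
        name=motif_name or "motif",
    )


def write_pwm(model: MotifModel, path) -> None:
    """Write a CIS-BP-style probability table (round-trips with load_pwm)."""
    with open(path, "w") as fh:
        fh.write("Pos\tA\tC\tG\tT\n")
        for i, row in enumerate(model.matrix, start=1):
            fh.write(f"{i}\t" + "\t".join(f"{p:.10g}" for p in row) + "\n")


def rbpj_consensus_pwm(
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> MotifModel:
    """Synthetic PWM for the canonical RBPJ binding site TGTGGGAAA.

    A consensus-based stand-in built programmatically (0.85 probability on
    the consensus base, 0.05 elsewhere), not a database matrix; it is sharp
    enough that two consensus mismatches (e.g. the GG -> cc mutation that
    abolishes RBPJ binding) always fall below the default calibrated
    threshold.
    """
    consensus = "TGTGGGAAA"
    m = np.full((len(consensus), 4), 0.05)
    for i, b in enumerate(consensus):
        m[i, _ALPHABET.index(b)] = 0.85
    return MotifModel(matrix=m, background=tuple(background), name="RBPJ")


@dataclass(frozen=True)
class ThresholdCalibration:
    """Exact null calibration of the integer PWM score.

    ``scores`` / ``tail`` tabulate P(S >= s) for every attainable integer
    score s (ascending).  ``threshold_int`` is the smallest score with tail
    probability <= alpha (max score + 1 if alpha is unattainably small).
    """

    threshold_int: int
    alpha: float
    scores: np.ndarray
    tail: np.ndarray

    @property
    def threshold(self) -> float:
        return self.threshold_int / SCORE_SCALE

    def tail_prob(self, score_int: int) -> float:
        """P(S >= score_int) under the background model."""
        i = np.searchsorted(self.scores, score_int, side="left")
        return float(self.tail[i]) if i < len(self.scores) else 0.0


def calibrate_threshold(model: MotifModel, alpha: float = 1e-4) -> ThresholdCalibration:
    """Exact score-threshold calibration by dynamic programming.

    Convolves the per-position integer score distributions under the
    background model, yielding the full null distribution of the motif score;
    no sampling and no approximation beyond the fixed score grid.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    ints = model.int_scores()
    bg = np.asarray(model.background)
    lo_off = int(ints.min(axis=1).sum())
    hi_off = int(ints.max(axis=1).sum())
    dist = np.zeros(hi_off - lo_off + 1)
    dist[0] = 1.0  # offset relative to lo_off, built up position by position
    cur_lo = 0
    cur_hi = 0
    for j in range(model.width):
        row = ints[j]
        rmin, rmax = int(row.min()), int(row.max())
        new = np.zeros_like(dist)
        for k in range(4):
            sh = int(row[k]) - rmin
            seg = dist[: cur_hi - cur_lo + 1]
            new[sh: sh + len(seg)] += bg[k] * seg
        dist = new
        cur_lo += rmin
        cur_hi += rmax
    support = np.nonzero(dist > 0)[0]
    scores = support + cur_lo
    probs = dist[support]
    tail = np.cumsum(probs[::-1])[::-1]
    idx = np.nonzero(tail <= alpha * (1 + 1e-12))[0]
    if len(idx) == 0:
        warnings.warn(
            "alpha below the minimal attainable tail probability; "
            "threshold set above the maximal score",
            stacklevel=2,
        )
        thr = int(scores[-1]) + 1
    else:
        thr = int(scores[idx[0]])
    return ThresholdCalibration(
        threshold_int=thr, alpha=alpha, scores=scores, tail=tail
    )


_SEQ_LUT = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(_ALPHABET):
    _SEQ_LUT[ord(_b)] = _i
    _SEQ_LUT[ord(_b.lower())] = _i


def _encode(seq: str) -> np.ndarray:
    return _SEQ_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _window_scores(codes: np.ndarray, ints: np.ndarray) -> np.ndarray:
    """Total integer score of every window; windows touching N are -inf-like."""
    w = ints.shape[0]
    n_win = len(codes) - w + 1
    # 5th column: sentinel for N far below any threshold
    lut = np.hstack([ints, np.full((w, 1), np.int64(-(1 << 40)))])
    total = np.zeros(n_win, dtype=np.int64)
    for j in range(w):
        total += lut[j][codes[j:j + n_win]]
    return total


def scan_sequence(
    seq: str,
    model: MotifModel,
    threshold: ThresholdCalibration | int,
    strands: str = "both",
    chrom: str = "seq",
) -> list[MotifHit]:
    """All PWM matches scoring at or above the calibrated threshold.

    The minus strand is scored on the reverse complement but reported in
    forward-strand half-open coordinates.  Windows overlapping an N are
    skipped.  Sequences shorter than the motif yield an empty list.
    """
    thr = threshold.threshold_int if isinstance(threshold, ThresholdCalibration) else int(threshold)
    w = model.width
    if len(seq) < w:
        return []
    codes = _encode(seq)
    ints = model.int_scores()
    hits: list[MotifHit] = []
    todo = []
    if strands in ("both", "+", "forward"):
        todo.append(("+", ints))
    if strands in ("both", "-", "reverse"):
        # score of revcomp(window) under the PWM, as a forward-sequence LUT
        rc = ints[::-1, ::-1].copy()
        todo.append(("-", rc))
    for strand, mat in todo:
        total = _window_scores(codes, mat)
        for i in np.nonzero(total >= thr)[0]:
            si = int(total[i])
            hits.append(
                MotifHit(chrom, int(i), int(i) + w, strand, si,
                         si / SCORE_SCALE)
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def window_around_tss(
    genes: Iterable[GenomicInterval],
    half_width: int = 10_000,
    chrom_sizes: dict[str, int] | None = None,
) -> list[GenomicInterval]:
    """Fixed windows [TSS - half_width, TSS + half_width) per gene.

    The TSS is ``start`` for '+' genes and ``end`` for '-' genes.  Windows are
    clipped at 0 on the left; right clipping requires ``chrom_sizes``.
    """
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    out = []
    for g in genes:
        if g.strand == "+":
            tss = g.start
        elif g.strand == "-":
            tss = g.end
        else:
            raise ValueError(f"gene {g.name!r} lacks a strand")
        start = max(0, tss - half_width)
        end = tss + half_width
        if chrom_sizes is not None:
            if g.chrom not in chrom_sizes:
                raise KeyError(
                    f"unknown chromosome length for {g.chrom!r}"
                )
            end = min(end, chrom_sizes[g.chrom])
        out.append(GenomicInterval(g.chrom, start, end, g.strand, g.name))
    return out


def intersect_contained(
    hits: Sequence, peaks: Sequence[GenomicInterval]
) -> list:
    """Keep hits fully contained in some peak (sweep over sorted peaks).

    For peaks sorted by start, the running maximum of peak ends among peaks
    with ``start <= hit.start`` reaches ``hit.end`` iff some single peak
    contains the hit (peaks are intervals, so the max-end peak among those
    starting early enough is a witness).
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    prepared = {}
    for chrom, ps in by_chrom.items():
        ps.sort(key=lambda p: p.start)
        starts = np.array([p.start for p in ps])
        run_max_end = np.maximum.accumulate(np.array([p.end for p in ps]))
        prepared[chrom] = (starts, run_max_end)
    kept = []
    for h in hits:
        pc = prepared.get(h.chrom)
        if pc is None:
            continue
        starts, run_max_end = pc
        i = int(np.searchsorted(starts, h.start, side="right")) - 1
        if i >= 0 and run_max_end[i] >= h.end:
            kept.append(h)
    return kept


@dataclass
class FilterReport:
    """Staged candidate-funnel counts plus per-gene detail."""

    n_deg: int
    n_with_motif: int
    n_in_open_chromatin: int
    per_gene: pd.DataFrame
    warnings: list[str] = field(default_factory=list)

    @property
    def funnel(self) -> tuple[int, int, int]:
        return (self.n_deg, self.n_with_motif, self.n_in_open_chromatin)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": [
                    "differentially_expressed",
                    "with_motif_in_window",
                    "motif_in_open_chromatin",
                ],
                "n_genes": list(self.funnel),
            }
        )


def _get_seq(genome, chrom: str, start: int, end: int) -> str:
    """Fetch genome[chrom][start:end], zero-clipped, from dict/str/Fasta."""
    if isinstance(genome, dict):
        s = genome[chrom]
        return s[max(0, start):min(len(s), end)]
    # pyfaidx.Fasta or similar mapping of chrom -> sliceable record
    rec = genome[chrom]
    return str(rec[max(0, start):end])


def candidate_filter_report(
    deg: pd.DataFrame,
    genes: Sequence[GenomicInterval],
    genome,
    pwm: MotifModel,
    peaks: Sequence[GenomicInterval],
    half_width: int = 10_000,
    alpha: float = 1e-4,
    adj_p_max: float = 0.05,
    min_abs_logfc: float = 1.0,
) -> FilterReport:
    """Run the staged candidate funnel over a differential-expression table.

    Stage 1 applies the significance filter (``adj_p < adj_p_max`` and
    ``|logFC| > min_abs_logfc``) to the input table; stage 2 keeps genes with
    at least one super-threshold PWM hit fully inside the TSS window; stage 3
    keeps genes whose best such hit (or any hit) is contained in an
    open-chromatin peak.  Genes missing coordinates are counted as no-motif
    and listed in the warnings.
    """
    deg = deg.copy()
    mask = (deg["adj_p"] < adj_p_max) & (deg["logFC"].abs() > min_abs_logfc)
    deg_sig = deg.loc[mask]
    gene_map = {g.name: g for g in genes}
    thr = calibrate_threshold(pwm, alpha=alpha)
    warn_list: list[str] = []
    detail = []
    n_with_motif = 0
    n_open = 0
    for _, row in deg_sig.iterrows():
        gid = row["gene_id"]
        g = gene_map.get(gid)
        if g is None:
            warn_list.append(f"gene {gid} missing coordinates; counted as no-motif")
            detail.append(
                {"gene_id": gid, "logFC": row["logFC"], "adj_p": row["adj_p"],
                 "has_motif": False, "in_open_chromatin": False,
                 "best_score": np.nan, "hit_start": pd.NA, "hit_end": pd.NA,
                 "hit_strand": pd.NA, "containing_peak": pd.NA}
            )
            continue
        win = window_around_tss([g], half_width=half_width)[0]
        seq = _get_seq(genome, win.chrom, win.start, win.end)
        raw_hits = scan_sequence(seq, pwm, thr, chrom=win.chrom)
        hits = [
            MotifHit(win.chrom, h.start + win.start, h.end + win.start,
                     h.strand, h.score_int, h.score)
            for h in raw_hits
        ]
        has_motif = len(hits) > 0
        contained = intersect_contained(hits, peaks) if has_motif else []
        in_open = len(contained) > 0
        n_with_motif += has_motif
        n_open += in_open
        best = max(hits, key=lambda h: h.score_int) if has_motif else None
        peak_name = pd.NA
        if in_open:
            best_open = max(contained, key=lambda h: h.score_int)
            for p in peaks:
                if (p.chrom == best_open.chrom and p.start <= best_open.start
                        and best_open.end <= p.end):
                    peak_name = p.name or f"{p.chrom}:{p.start}-{p.end}"
                    break
        detail.append(
            {
                "gene_id": gid,
                "logFC": row["logFC"],
                "adj_p": row["adj_p"],
                "has_motif": has_motif,
                "in_open_chromatin": in_open,
                "best_score": best.score if best else np.nan,
                "hit_start": best.start if best else pd.NA,
                "hit_end": best.end if best else pd.NA,
                "hit_strand": best.strand if best else pd.NA,
                "containing_peak": peak_name,
            }
        )
    per_gene = pd.DataFrame(
        detail,
        columns=["gene_id", "logFC", "adj_p", "has_motif",
                 "in_open_chromatin", "best_score", "hit_start", "hit_end",
                 "hit_strand", "containing_peak"],
    )
    return FilterReport(
        n_deg=int(len(deg_sig)),
        n_with_motif=int(n_with_motif),
        n_in_open_chromatin=int(n_open),
        per_gene=per_gene,
        warnings=warn_list,
    )


# ---------------------------------------------------------------------------
# BED helpers (plain 6-column text via pandas)


def read_bed(path) -> list[GenomicInterval]:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str},
    )
    out = []
    for _, r in df.iterrows():
        strand = r["strand"] if isinstance(r["strand"], str) else "."
        name = r["name"] if isinstance(r["name"], str) else ""
        out.append(GenomicInterval(r["chrom"], int(r["start"]), int(r["end"]),
                                   strand, name))
    return out


def write_bed(intervals: Iterable, path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            name = getattr(iv, "name", "") or "."
            strand = getattr(iv, "strand", ".") or "."
            score = getattr(iv, "score_int", 0)
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{strand}\n"
            )
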