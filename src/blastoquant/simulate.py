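"""Synthetic data generators with known ground truth.

Three generators stand in for the raw data of a preimplantation-embryo
imaging/genomics study:

* :func:`simulate_embryo_series` — live-imaged morula→blastocyst movies:
  dividing cells on an ellipsoidal embryo, inner/outer shells, a nuclear
  reporter whose level depends on the cell's current position, multiplicative
  depth (z) attenuation, and a tracking edge list.
* :func:`simulate_fixed_cohort` — a single-timepoint multi-embryo cohort with
  three linearly coupled marker channels, for correlation analyses.
* :func:`simulate_genome_fixture` — a small genome with genes, open-chromatin
  peaks, a differential-expression table and transcription-factor binding
  sites planted at known coordinates, for the motif-scanning funnel.

Every generator is deterministic given its seed; all randomness flows from a
single :class:`numpy.random.SeedSequence` with per-embryo substreams.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ChannelModel",
    "SimParams",
    "CohortCoupling",
    "GenomeFixtureParams",
    "PlantedMotif",
    "SimTruth",
    "GenomeFixture",
    "simulate_embryo_series",
    "simulate_fixed_cohort",
    "simulate_genome_fixture",
    "write_genome_fixture",
    "cohort_pairwise_r2",
    "cohort_multiple_r2",
    "INNER_BAND",
    "OUTER_BAND",
]

#: normalized-radius band in which inner cells are placed
INNER_BAND = (0.0, 0.6)
#: normalized-radius band (surface shell) in which outer cells are placed
OUTER_BAND = (0.8, 1.0)

NUCLEUS_COLUMNS = ["embryo_id", "cell_id", "frame", "x_um", "y_um", "z_um"]
TRACK_COLUMNS = ["embryo_id", "child_id", "parent_id", "frame"]


class ChannelModel(NamedTuple):
    """Log-scale intensity trajectory of one marker channel.

    ``mean_in``/``mean_out`` are log-intensity intercepts for cells currently
    in an inner/outer position; ``slope_in``/``slope_out`` are per-frame log
    drifts; ``noise_sd`` is the per-observation Gaussian sd on the log scale.
    """

    mean_in: float
    mean_out: float
    slope_in: float
    slope_out: float
    noise_sd: float


#: Default three-channel model.  ch1 mimics a Notch-activity reporter
#: (higher and rising outside, lower and falling inside); ch2 is a
#: position-independent control; ch3 mimics a TE factor (outer-biased).
DEFAULT_CHANNELS = (
    ChannelModel(4.0, 4.6, -0.015, 0.015, 0.25),
    ChannelModel(4.2, 4.2, 0.0, 0.0, 0.30),
    ChannelModel(4.1, 4.5, 0.0, 0.010, 0.30),
)


@dataclass
class SimParams:
    """Parameters of the live-embryo simulator.

    Defaults emulate the study conditions of the time-lapse arm: 7 embryos
    imaged from the 16-cell compacted morula to the ~32-cell early
    blastocyst, ~25% of cells inner, rare repositioning events, confocal
    z-attenuation of ~1%/µm and 1 µm centroid noise.
    """

    seed: int = 0
    n_embryos: int = 7
    n_cells_start: int = 16
    n_cells_end: int = 32
    n_frames: int = 25
    division_rate: float = 0.04
    inner_fraction: float = 0.25
    ellipsoid_axes: tuple[float, float, float] = (30.0, 25.0, 20.0)
    channel_model: tuple[ChannelModel, ...] = DEFAULT_CHANNELS
    z_decay: float = 0.01
    reposition_prob: float = 0.02
    centroid_noise_sd: float = 1.0

    def __post_init__(self) -> None:
        self.channel_model = tuple(
            ChannelModel(*c) for c in self.channel_model
        )
        scalars = [
            self.division_rate, self.inner_fraction, self.z_decay,
            self.reposition_prob, self.centroid_noise_sd,
            *self.ellipsoid_axes,
        ] + [v for c in self.channel_model for v in c]
        if not all(math.isfinite(v) for v in scalars):
            raise ValueError("SimParams contains non-finite values")
        if not 0.0 < self.inner_fraction < 1.0:
            raise ValueError("inner_fraction must be in (0, 1)")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.n_cells_end < self.n_cells_start:
            raise ValueError("n_cells_end must be >= n_cells_start")
        if any(a <= 0 for a in self.ellipsoid_axes):
            raise ValueError("ellipsoid axes must be positive")
        if any(c.noise_sd < 0 for c in self.channel_model):
            raise ValueError("channel noise_sd must be >= 0")
        if not 0.0 <= self.division_rate <= 1.0:
            raise ValueError("division_rate must be a probability")
        if not 0.0 <= self.reposition_prob <= 1.0:
            raise ValueError("reposition_prob must be a probability")
        if self.centroid_noise_sd < 0:
            raise ValueError("centroid_noise_sd must be >= 0")


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated movie.

    ``labels``: one row per (embryo, cell, frame) with the true inner/outer
    state.  ``families``: one row per founder family with the founder's
    frame-0 label, the realized fate class and the number of shell switches
    that occurred in the family.
    """

    labels: pd.DataFrame
    families: pd.DataFrame


def _true_family_class(founder_label: str, leaf_labels: Sequence[str]) -> str:
    if len(leaf_labels) == 0:
        return "UNCLASSIFIABLE"
    all_in = all(l == "inner" for l in leaf_labels)
    all_out = all(l == "outer" for l in leaf_labels)
    if founder_label == "inner":
        if all_in:
            return "IN-ICM"
        if all_out:
            return "OTHER"
        return "IN-TE+ICM"
    if all_out:
        return "OUT-TE"
    if all_in:
        return "OTHER"
    return "OUT-TE+ICM"


def _sample_radius(rng: np.random.Generator, inner: np.ndarray) -> np.ndarray:
    lo = np.where(inner, INNER_BAND[0], OUTER_BAND[0])
    hi = np.where(inner, INNER_BAND[1], OUTER_BAND[1])
    return rng.uniform(lo, hi)


def _unit_dirs(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def simulate_embryo_series(
    params: SimParams,
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Simulate live-imaged embryos and return (nuclei, tracks, truth).

    The nucleus table has one row per (cell, frame) with observed centroid
    (true position + centroid noise) and observed channel intensities
    ``exp(mu_shell(t) + eps) * exp(-z_decay * z)``.  The tracking table has
    one edge per non-founder cell-frame: continuation edges carry
    ``child_id == parent_id``; the two daughters of a division carry fresh
    ids and point to the parent cell.
    """
    axes = np.asarray(params.ellipsoid_axes, dtype=float)
    center = axes + 10.0  # keep the embryo away from the coordinate origin
    streams = np.random.SeedSequence(params.seed).spawn(params.n_embryos)

    nuc_parts: list[pd.DataFrame] = []
    trk_parts: list[pd.DataFrame] = []
    lab_parts: list[pd.DataFrame] = []
    fam_rows: list[dict] = []

    for e in range(params.n_embryos):
        rng = np.random.default_rng(streams[e])
        embryo_id = f"E{e:02d}"
        n = params.n_cells_start
        inner = rng.random(n) < params.inner_fraction
        r = _sample_radius(rng, inner)
        dirs = _unit_dirs(rng, n)
        ids = np.arange(n)
        family = ids.copy()
        next_id = n
        founder_label = {int(i): ("inner" if inner[k] else "outer")
                         for k, i in enumerate(ids)}
        switches: dict[int, int] = {int(f): 0 for f in family}

        rows: list[dict] = []
        edges: list[tuple] = []
        labels: list[tuple] = []

        for t in range(params.n_frames):
            pos = center + r[:, None] * (axes[None, :] * dirs)
            obs = pos
            if params.centroid_noise_sd > 0:
                obs = pos + rng.normal(
                    0.0, params.centroid_noise_sd, size=pos.shape
                )
            decay = np.exp(-params.z_decay * pos[:, 2])
            chans = []
            for cm in params.channel_model:
                mu = np.where(
                    inner,
                    cm.mean_in + cm.slope_in * t,
                    cm.mean_out + cm.slope_out * t,
                )
                if cm.noise_sd > 0:
                    mu = mu + rng.normal(0.0, cm.noise_sd, size=mu.shape)
                chans.append(np.exp(mu) * decay)
            frame_df = {
                "embryo_id": embryo_id,
                "cell_id": ids.copy(),
                "frame": t,
                "x_um": obs[:, 0],
                "y_um": obs[:, 1],
                "z_um": obs[:, 2],
            }
            for c, v in enumerate(chans, start=1):
                frame_df[f"ch{c}"] = v
            rows.append(pd.DataFrame(frame_df))
            labels.extend(
                (embryo_id, int(i), t, "inner" if inn else "outer", int(f))
                for i, inn, f in zip(ids, inner, family)
            )

            if t == params.n_frames - 1:
                break

            # divisions (capped at n_cells_end)
            divide = rng.random(len(ids)) < params.division_rate
            capacity = params.n_cells_end - len(ids)
            div_idx = np.flatnonzero(divide)
            if len(div_idx) > capacity:
                div_idx = rng.permutation(div_idx)[:capacity]
            div_mask = np.zeros(len(ids), dtype=bool)
            div_mask[div_idx] = True

            keep = ~div_mask
            new_ids = [ids[keep]]
            new_family = [family[keep]]
            new_inner = [inner[keep]]
            new_r = [r[keep]]
            new_dirs = [dirs[keep]]
            for i, cid in zip(np.flatnonzero(div_mask), ids[div_mask]):
                d_ids = np.array([next_id, next_id + 1])
                next_id += 2
                new_ids.append(d_ids)
                new_family.append(np.array([family[i], family[i]]))
                new_inner.append(np.array([inner[i], inner[i]]))
                # daughters sit at the parent position +- a small jitter
                d_r = np.clip(
                    r[i] + rng.normal(0.0, 0.02, size=2),
                    INNER_BAND[0] if inner[i] else OUTER_BAND[0],
                    INNER_BAND[1] if inner[i] else OUTER_BAND[1],
                )
                d_dirs = dirs[i] + rng.normal(0.0, 0.08, size=(2, 3))
                d_dirs /= np.linalg.norm(d_dirs, axis=1, keepdims=True)
                new_r.append(d_r)
                new_dirs.append(d_dirs)
                edges.extend(
                    (embryo_id, int(d), int(cid), t + 1) for d in d_ids
                )
            edges.extend(
                (embryo_id, int(c), int(c), t + 1) for c in ids[keep]
            )
            ids = np.concatenate(new_ids)
            family = np.concatenate(new_family)
            inner = np.concatenate(new_inner)
            r = np.concatenate(new_r)
            dirs = np.concatenate(new_dirs)
            m = len(ids)

            # rare inner/outer repositioning: Bernoulli shell switch
            if params.reposition_prob > 0:
                sw = rng.random(m) < params.reposition_prob
                if sw.any():
                    inner = np.where(sw, ~inner, inner)
                    r_new = _sample_radius(rng, inner)
                    r = np.where(sw, r_new, r)
                    for f in family[sw]:
                        switches[int(f)] += 1

        # family ground truth from realized labels
        leaf_labels: dict[int, list[str]] = {int(f): [] for f in founder_label}
        for i, inn, f in zip(ids, inner, family):
            leaf_labels[int(f)].append("inner" if inn else "outer")
        for f, flab in founder_label.items():
            fam_rows.append(
                {
                    "embryo_id": embryo_id,
                    "family_id": f,
                    "founder_label": flab,
                    "true_class": _true_family_class(flab, leaf_labels[f]),
                    "n_switches": switches[f],
                }
            )

        nuc_parts.append(pd.concat(rows, ignore_index=True))
        trk_parts.append(pd.DataFrame(edges, columns=TRACK_COLUMNS))
        lab_parts.append(
            pd.DataFrame(
                labels,
                columns=["embryo_id", "cell_id", "frame", "true_label",
                         "family_id"],
            )
        )

    nuclei = pd.concat(nuc_parts, ignore_index=True)
    tracks = (
        pd.concat(trk_parts, ignore_index=True)
        if trk_parts
        else pd.DataFrame(columns=TRACK_COLUMNS)
    )
    truth = SimTruth(
        labels=pd.concat(lab_parts, ignore_index=True),
        families=pd.DataFrame(fam_rows),
    )
    return nuclei, tracks, truth


# ---------------------------------------------------------------------------
# fixed-cohort generator


@dataclass
class CohortCoupling:
    """Linear coupling ``ch3 = a*ch1 + b*ch2 + N(0, noise_sd^2)``."""

    a: float = 1.0
    b: float = 1.0
    noise_sd: float = math.sqrt(0.5) * 10.0
    ch1_mean: float = 100.0
    ch1_sd: float = 10.0
    ch2_mean: float = 100.0
    ch2_sd: float = 10.0
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("negative noise sd")
        if self.ch1_sd <= 0 or self.ch2_sd <= 0:
            raise ValueError("channel sds must be positive")


def cohort_pairwise_r2(coupling: CohortCoupling) -> tuple[float, float]:
    """Population R² of ch3 against ch1 and against ch2, in closed form."""
    v1 = coupling.a**2 * coupling.ch1_sd**2
    v2 = coupling.b**2 * coupling.ch2_sd**2
    v3 = v1 + v2 + coupling.noise_sd**2
    if v3 == 0:
        return 0.0, 0.0
    return v1 / v3, v2 / v3


def cohort_multiple_r2(coupling: CohortCoupling) -> float:
    """Population coefficient of determination of ch3 on (ch1, ch2)."""
    v1 = coupling.a**2 * coupling.ch1_sd**2
    v2 = coupling.b**2 * coupling.ch2_sd**2
    v3 = v1 + v2 + coupling.noise_sd**2
    return 0.0 if v3 == 0 else (v1 + v2) / v3


def simulate_fixed_cohort(
    params: SimParams, coupling: CohortCoupling | None = None
) -> pd.DataFrame:
    """Single-frame multi-embryo nucleus table with coupled channels.

    Positions are sampled on the same inner/outer shells as the movie
    generator; intensities are Gaussian on the raw scale with
    ``ch3 = a*ch1 + b*ch2 + noise``.  If ``params.z_decay > 0`` every channel
    is additionally attenuated by ``exp(-z_decay*z)`` (off by default for
    correlation studies).
    """
    if coupling is None:
        coupling = CohortCoupling()
    axes = np.asarray(params.ellipsoid_axes, dtype=float)
    center = axes + 10.0
    streams = np.random.SeedSequence(params.seed).spawn(params.n_embryos)
    parts = []
    for e in range(params.n_embryos):
        rng = np.random.default_rng(streams[e])
        n = params.n_cells_start
        inner = rng.random(n) < params.inner_fraction
        r = _sample_radius(rng, inner)
        dirs = _unit_dirs(rng, n)
        pos = center + r[:, None] * (axes[None, :] * dirs)
        obs = pos
        if params.centroid_noise_sd > 0:
            obs = pos + rng.normal(0, params.centroid_noise_sd, pos.shape)
        ch1 = rng.normal(coupling.ch1_mean, coupling.ch1_sd, n)
        ch2 = rng.normal(coupling.ch2_mean, coupling.ch2_sd, n)
        ch3 = (
            coupling.intercept
            + coupling.a * ch1
            + coupling.b * ch2
            + (rng.normal(0, coupling.noise_sd, n) if coupling.noise_sd > 0
               else 0.0)
        )
        if params.z_decay > 0:
            decay = np.exp(-params.z_decay * pos[:, 2])
            ch1, ch2, ch3 = ch1 * decay, ch2 * decay, ch3 * decay
        parts.append(
            pd.DataFrame(
                {
                    "embryo_id": f"E{e:02d}",
                    "cell_id": np.arange(n),
                    "frame": 0,
                    "x_um": obs[:, 0],
                    "y_um": obs[:, 1],
                    "z_um": obs[:, 2],
                    "ch1": ch1,
                    "ch2": ch2,
                    "ch3": ch3,
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# genome fixture generator


class PlantedMotif(NamedTuple):
    """A binding site planted for one gene: offset is relative to the TSS."""

    gene_index: int
    offset: int
    strand: str = "+"
    in_peak: bool = True


@dataclass
class GenomeFixtureParams:
    seed: int = 0
    genome_length: int = 200_000
    n_genes: int = 6
    n_peaks: int = 8
    peak_width: int = 400
    planted_motifs: tuple[PlantedMotif, ...] | None = None
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    gene_length: int = 1000
    half_width: int = 10_000
    alpha: float = 1e-4

    def __post_init__(self) -> None:
        if abs(sum(self.background) - 1.0) > 1e-12:
            raise ValueError("background frequencies must sum to 1")
        if self.planted_motifs is not None:
            self.planted_motifs = tuple(
                PlantedMotif(*m) for m in self.planted_motifs
            )
            for m in self.planted_motifs:
                if not 0 <= m.gene_index < self.n_genes:
                    raise ValueError(f"gene_index {m.gene_index} out of range")
                if abs(m.offset) > self.half_width:
                    raise ValueError("planted offset outside the TSS window")


@dataclass
class GenomeFixture:
    """In-memory genome fixture plus its construction ground truth."""

    chrom: str
    sequence: str
    genes: pd.DataFrame        # BED6-like: chrom start end name score strand
    peaks: pd.DataFrame
    deg: pd.DataFrame          # gene_id, logFC, adj_p
    planted: pd.DataFrame      # gene_id, start, end, strand, in_peak
    expected_funnel: tuple[int, int, int]
    half_width: int
    alpha: float


_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def simulate_genome_fixture(params: GenomeFixtureParams, pwm=None) -> GenomeFixture:
    """Build a genome whose only super-threshold motif hits are the planted ones.

    Background sequence is rejection-resampled until a full two-strand scan at
    the exactly calibrated threshold finds no hits outside the planted
    footprints.  Genes are spaced so TSS windows never overlap; peaks either
    contain a planted site (``in_peak``) or avoid all planted sites.
    """
    from .regulatory import calibrate_threshold, rbpj_consensus_pwm, scan_sequence

    if pwm is None:
        pwm = rbpj_consensus_pwm()
    w = pwm.width
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))

    lead = params.half_width + params.gene_length + 1000
    spacing = 2 * params.half_width + params.gene_length + 2000
    required = lead + (params.n_genes - 1) * spacing + params.half_width + \
        params.gene_length + 1000
    if params.genome_length < required:
        raise ValueError(
            f"genome_length {params.genome_length} too short for "
            f"{params.n_genes} genes with {params.half_width} bp windows "
            f"(need >= {required})"
        )

    # genes: alternate strands; TSS = start on '+', end on '-'
    gene_rows = []
    tss = np.empty(params.n_genes, dtype=int)
    for i in range(params.n_genes):
        t = lead + i * spacing
        strand = "+" if i % 2 == 0 else "-"
        if strand == "+":
            start, end = t, t + params.gene_length
        else:
            start, end = t - params.gene_length, t
        tss[i] = t
        gene_rows.append(
            {"chrom": "chr1", "start": start, "end": end,
             "name": f"gene_{i:03d}", "score": 0, "strand": strand}
        )
    genes = pd.DataFrame(gene_rows)

    planted = params.planted_motifs
    if planted is None:
        planted = tuple(
            PlantedMotif(i, -2500, "+", True) for i in range(params.n_genes)
        )
    consensus = pwm.consensus
    planted_rows = []
    for m in planted:
        if m.offset > params.half_width - w:
            raise ValueError("planted motif would extend past its window")
        s = int(tss[m.gene_index] + m.offset)
        planted_rows.append(
            {"gene_id": f"gene_{m.gene_index:03d}", "start": s, "end": s + w,
             "strand": m.strand, "in_peak": bool(m.in_peak)}
        )
    planted_df = pd.DataFrame(
        planted_rows,
        columns=["gene_id", "start", "end", "strand", "in_peak"],
    )

    # background sequence
    L = params.genome_length
    bases = np.frombuffer(b"ACGT", dtype="S1")
    seq = rng.choice(4, size=L, p=np.asarray(params.background))
    protected = np.zeros(L, dtype=bool)
    b2i = {65: 0, 67: 1, 71: 2, 84: 3}
    for row in planted_rows:
        site = consensus if row["strand"] == "+" else _revcomp(consensus)
        idx = np.array([b2i[ord(c)] for c in site])
        seq[row["start"]:row["end"]] = idx
        protected[row["start"]:row["end"]] = True

    thr = calibrate_threshold(pwm, alpha=params.alpha)
    planted_iv = {(r["start"], r["end"]) for r in planted_rows}
    for _ in range(100):
        s = bases[seq].tobytes().decode("ascii")
        hits = scan_sequence(s, pwm, thr)
        extra = [h for h in hits if (h.start, h.end) not in planted_iv]
        if not extra:
            break
        for h in extra:
            pos = np.arange(h.start, h.end)
            pos = pos[~protected[pos]]
            seq[pos] = rng.choice(4, size=len(pos),
                                  p=np.asarray(params.background))
    else:
        raise RuntimeError(
            "could not rejection-sample a background free of chance hits"
        )
    sequence = bases[seq].tobytes().decode("ascii")

    # peaks: one per in_peak planted site, remainder placed away from sites
    peak_rows = []
    n_site_peaks = sum(1 for r in planted_rows if r["in_peak"])
    if n_site_peaks > params.n_peaks:
        raise ValueError("n_peaks smaller than the number of in_peak motifs")
    for r in planted_rows:
        if not r["in_peak"]:
            continue
        pstart = max(0, r["start"] - (params.peak_width - w) // 2)
        peak_rows.append((pstart, pstart + params.peak_width))
    motif_iv = [(r["start"], r["end"]) for r in planted_rows]
    attempts = 0
    while len(peak_rows) < params.n_peaks and attempts < 5000:
        attempts += 1
        pstart = int(rng.integers(0, L - params.peak_width))
        pend = pstart + params.peak_width
        if any(pstart < e and s_ < pend for s_, e in motif_iv):
            continue
        if any(pstart < e and s_ < pend for s_, e in peak_rows):
            continue
        peak_rows.append((pstart, pend))
    peaks = pd.DataFrame(
        [
            {"chrom": "chr1", "start": s_, "end": e,
             "name": f"peak_{k:03d}", "score": 0, "strand": "."}
            for k, (s_, e) in enumerate(sorted(peak_rows))
        ],
        columns=["chrom", "start", "end", "name", "score", "strand"],
    )

    # DEG table: every gene differentially expressed (alternating sign)
    deg = pd.DataFrame(
        {
            "gene_id": [f"gene_{i:03d}" for i in range(params.n_genes)],
            "logFC": [2.5 if i % 2 == 0 else -2.5
                      for i in range(params.n_genes)],
            "adj_p": 1e-4,
        }
    )

    n_deg = params.n_genes
    with_motif = {r["gene_id"] for r in planted_rows}
    in_peak = {r["gene_id"] for r in planted_rows if r["in_peak"]}
    fixture = GenomeFixture(
        chrom="chr1",
        sequence=sequence,
        genes=genes,
        peaks=peaks,
        deg=deg,
        planted=planted_df,
        expected_funnel=(n_deg, len(with_motif), len(in_peak)),
        half_width=params.half_width,
        alpha=params.alpha,
    )
    return fixture


def write_genome_fixture(fixture: GenomeFixture, outdir) -> dict:
    """Write FASTA / BED / TSV files for a fixture; return the paths."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "fasta": os.path.join(outdir, "genome.fa"),
        "genes": os.path.join(outdir, "genes.bed"),
        "peaks": os.path.join(outdir, "peaks.bed"),
        "deg": os.path.join(outdir, "deg.tsv"),
    }
    with open(paths["fasta"], "w") as fh:
        fh.write(f">{fixture.chrom}\n")
        s = fixture.sequence
        for i in range(0, len(s), 60):
            fh.write(s[i:i + 60] + "\n")
    fixture.genes.to_csv(paths["genes"], sep="\t", header=False, index=False)
    fixture.peaks.to_csv(paths["peaks"], sep="\t", header=False, index=False)
    fixture.deg.to_csv(paths["deg"], sep="\t", index=False)
    return paths
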