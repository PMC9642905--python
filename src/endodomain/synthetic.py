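"""Ground-truthed synthetic data: coelomocyte scenes, FRAP series, sequences, hit tables.

The scene generator renders a disc-shaped cell with a central nucleus and
peripheral ring-shaped endosomes carrying angular microdomain arcs.  Rendering
is deliberately piecewise constant (no anti-aliasing, additive Gaussian noise
clipped at zero) so that every downstream metric can be predicted analytically
from the spec in the noise-free case.

Arc convention: a ring pixel belongs to the microdomain iff the angle of its
center from the endosome center (degrees CCW from +x, image y down) lies in
``[arc_center - 180*coverage, arc_center + 180*coverage)`` modulo 360.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from endodomain.iwn import DEFAULT_HYDROPHILIC, SequenceRecord
from endodomain.roi import DiscROI, PixelImage, RingROI

__all__ = [
    "EndosomeSpec",
    "SceneSpec",
    "FrapSpec",
    "SequenceFixtureSpec",
    "SceneTruth",
    "generate_coelomocyte",
    "generate_frap_series",
    "generate_sequence_fixtures",
    "generate_blast_table",
    "arc_contains",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def _as_tuple(x) -> tuple[float, ...]:
    if np.isscalar(x):
        return (float(x),)
    return tuple(float(v) for v in x)


@dataclass(frozen=True)
class EndosomeSpec:
    """One ring-shaped endosome with a per-channel microdomain arc.

    Per-channel fields (``ring_intensity``, ``arc_center_deg``,
    ``arc_coverage``, ``arc_intensity``) accept a scalar (one channel) or a
    sequence with one entry per channel.
    """

    center: tuple[float, float]
    radius_um: float
    ring_width_um: float
    ring_intensity: tuple[float, ...]
    arc_center_deg: tuple[float, ...]
    arc_coverage: tuple[float, ...]
    arc_intensity: tuple[float, ...]

    def __post_init__(self) -> None:
        for name in ("ring_intensity", "arc_center_deg", "arc_coverage", "arc_intensity"):
            object.__setattr__(self, name, _as_tuple(getattr(self, name)))
        n = len(self.ring_intensity)
        for name in ("arc_center_deg", "arc_coverage", "arc_intensity"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} must have one entry per channel ({n})")
        if not self.radius_um > self.ring_width_um / 2 > 0:
            raise ValueError("need radius_um > ring_width_um/2 > 0")
        for cov in self.arc_coverage:
            if not 0 <= cov <= 1:
                raise ValueError("arc_coverage must lie in [0, 1]")

    @property
    def n_channels(self) -> int:
        return len(self.ring_intensity)

    @property
    def outer_radius_um(self) -> float:
        return self.radius_um + self.ring_width_um / 2

    def as_ring(self) -> RingROI:
        return RingROI(
            center=self.center, radius_um=self.radius_um, width_um=self.ring_width_um
        )


@dataclass(frozen=True)
class SceneSpec:
    """Full parametric description of a synthetic coelomocyte scene."""

    cell_center: tuple[float, float]
    cell_radius_um: float
    nucleus_radius_um: float
    cytoplasm_intensity: float
    background_intensity: float
    endosomes: tuple[EndosomeSpec, ...]
    noise_sd: float
    pixel_size_um: float
    image_shape: tuple[int, int]
    seed: int
    nucleus_intensity: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "endosomes", tuple(self.endosomes))
        if self.nucleus_intensity is None:
            object.__setattr__(self, "nucleus_intensity", self.cytoplasm_intensity / 2)
        if not 0 < self.nucleus_radius_um < self.cell_radius_um:
            raise ValueError("need 0 < nucleus_radius_um < cell_radius_um")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for name in ("cytoplasm_intensity", "background_intensity", "nucleus_intensity"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        cx, cy = self.cell_center
        r_px = self.cell_radius_um / self.pixel_size_um
        nrow, ncol = self.image_shape
        if cx - r_px < 0 or cy - r_px < 0 or cx + r_px > ncol - 1 or cy + r_px > nrow - 1:
            raise ValueError("cell disc does not fit inside the image bounds")
        n_ch = {e.n_channels for e in self.endosomes}
        if len(n_ch) > 1:
            raise ValueError("all endosomes must declare the same number of channels")
        for i, e in enumerate(self.endosomes):
            d_um = np.hypot(cx - e.center[0], cy - e.center[1]) * self.pixel_size_um
            if d_um + e.outer_radius_um > self.cell_radius_um:
                raise ValueError(
                    f"endosome {i} at {e.center} extends outside the cell disc"
                )

    @property
    def n_channels(self) -> int:
        return self.endosomes[0].n_channels if self.endosomes else 1

    def cell_roi(self) -> DiscROI:
        return DiscROI(center=self.cell_center, radius_um=self.cell_radius_um)

    def nucleus_roi(self) -> DiscROI:
        return DiscROI(center=self.cell_center, radius_um=self.nucleus_radius_um)


@dataclass(frozen=True)
class SceneTruth:
    """Ground truth sufficient to predict every metric on the noise-free scene."""

    cell: DiscROI
    nucleus: DiscROI
    rings: tuple[RingROI, ...]
    arc_table: pd.DataFrame


def arc_contains(angles_deg: np.ndarray, arc_center_deg: float, coverage: float) -> np.ndarray:
    """Membership of angles in ``[center - 180*cov, center + 180*cov)`` mod 360."""
    if coverage <= 0:
        return np.zeros_like(np.asarray(angles_deg, dtype=float), dtype=bool)
    start = arc_center_deg - 180.0 * coverage
    return np.mod(np.asarray(angles_deg, dtype=float) - start, 360.0) < 360.0 * coverage


def generate_coelomocyte(spec: SceneSpec) -> tuple[list[PixelImage], SceneTruth]:
    """Render a multi-channel coelomocyte scene and its ground truth.

    Returns one :class:`PixelImage` per channel plus a :class:`SceneTruth`
    holding the cell/nucleus/endosome ROIs and the per-channel arc table.
    Identical spec (including seed) reproduces bit-identical pixels.
    """
    nrow, ncol = spec.image_shape
    rows, cols = np.ogrid[:nrow, :ncol]
    cx, cy = spec.cell_center
    px = spec.pixel_size_um
    dist_cell = np.hypot(cols - cx, rows - cy) * px + np.zeros((nrow, ncol))

    base = np.full((nrow, ncol), spec.background_intensity, dtype=float)
    base[dist_cell <= spec.cell_radius_um] = spec.cytoplasm_intensity
    base[dist_cell <= spec.nucleus_radius_um] = spec.nucleus_intensity

    channels = [base.copy() for _ in range(spec.n_channels)]
    for e in spec.endosomes:
        ex, ey = e.center
        d = np.hypot(cols - ex, rows - ey) * px + np.zeros((nrow, ncol))
        in_ring = np.abs(d - e.radius_um) <= e.ring_width_um / 2
        ang = np.mod(np.degrees(np.arctan2(ey - rows, cols - ex)), 360.0) + np.zeros(
            (nrow, ncol)
        )
        for ch in range(spec.n_channels):
            in_arc = in_ring & arc_contains(
                ang, e.arc_center_deg[ch], e.arc_coverage[ch]
            )
            channels[ch][in_ring] = e.ring_intensity[ch]
            channels[ch][in_arc] = e.arc_intensity[ch]

    if spec.noise_sd > 0:
        streams = np.random.SeedSequence(spec.seed).spawn(spec.n_channels)
        for ch in range(spec.n_channels):
            rng = np.random.default_rng(streams[ch])
            channels[ch] = np.clip(
                channels[ch] + rng.normal(0, spec.noise_sd, size=(nrow, ncol)), 0, None
            )

    arc_rows = []
    for i, e in enumerate(spec.endosomes):
        row: dict[str, float] = {
            "endosome": i,
            "center_x": e.center[0],
            "center_y": e.center[1],
            "radius_um": e.radius_um,
            "ring_width_um": e.ring_width_um,
        }
        for ch in range(spec.n_channels):
            row[f"ch{ch}_ring_intensity"] = e.ring_intensity[ch]
            row[f"ch{ch}_arc_center_deg"] = e.arc_center_deg[ch]
            row[f"ch{ch}_arc_coverage"] = e.arc_coverage[ch]
            row[f"ch{ch}_arc_intensity"] = e.arc_intensity[ch]
        arc_rows.append(row)
    truth = SceneTruth(
        cell=spec.cell_roi(),
        nucleus=spec.nucleus_roi(),
        rings=tuple(e.as_ring() for e in spec.endosomes),
        arc_table=pd.DataFrame(arc_rows),
    )
    return [PixelImage(values=c, pixel_size_um=px) for c in channels], truth


# ---------------------------------------------------------------------------
# FRAP series
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FrapSpec:
    """Parameters of a synthetic photobleaching time series.

    The bleach-region signal follows
    ``I(t) = floor + span * mobile_fraction * (1 - exp(-t/tau))`` after the
    bleach, with ``floor = prebleach * (1 - bleach_depth)`` and
    ``span = prebleach - floor``; the whole signal (not the camera offset)
    fades by ``(1 - acquisition_bleach_rate)`` per frame.
    """

    n_frames: int
    frame_interval_s: float
    bleach_frame: int
    prebleach_intensity: float
    bleach_depth: float
    mobile_fraction: float
    tau_s: float
    acquisition_bleach_rate: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0
    background_level: float = 5.0
    frame_shape: tuple[int, int] = (64, 64)
    pixel_size_um: float = 0.1

    def __post_init__(self) -> None:
        if not 0 <= self.mobile_fraction <= 1:
            raise ValueError("mobile_fraction must lie in [0, 1]")
        if not self.tau_s > 0:
            raise ValueError("tau_s must be positive")
        if not 0 < self.bleach_frame < self.n_frames:
            raise ValueError("need 0 < bleach_frame < n_frames")
        if not 0 <= self.bleach_depth <= 1:
            raise ValueError("bleach_depth must lie in [0, 1]")
        if self.noise_sd < 0 or self.acquisition_bleach_rate < 0:
            raise ValueError("noise_sd and acquisition_bleach_rate must be >= 0")

    def bleach_signal(self, frame: int) -> float:
        """Unfaded bleach-region signal at a given frame index."""
        if frame < self.bleach_frame:
            return self.prebleach_intensity
        floor = self.prebleach_intensity * (1 - self.bleach_depth)
        span = self.prebleach_intensity - floor
        t = (frame - self.bleach_frame) * self.frame_interval_s
        return floor + span * self.mobile_fraction * (1 - np.exp(-t / self.tau_s))


def generate_frap_series(
    spec: FrapSpec,
) -> tuple[list[PixelImage], dict[str, DiscROI]]:
    """Render a FRAP time series with bleach, reference, and background ROIs.

    Frames contain a constant camera offset (``background_level``) plus two
    disc signals: the bleach disc following the recovery model and a reference
    disc at the pre-bleach level; both are scaled by the per-frame acquisition
    fade.  The background ROI sits on offset-only pixels.
    """
    nrow, ncol = spec.frame_shape
    px = spec.pixel_size_um
    disc_r_um = min(nrow, ncol) * px / 8
    rois = {
        "bleach": DiscROI(center=(ncol * 0.25, nrow * 0.5), radius_um=disc_r_um),
        "reference": DiscROI(center=(ncol * 0.75, nrow * 0.5), radius_um=disc_r_um),
        "background": DiscROI(center=(ncol * 0.5, nrow * 0.1), radius_um=disc_r_um),
    }
    rows, cols = np.ogrid[:nrow, :ncol]

    def _mask(roi: DiscROI) -> np.ndarray:
        return (
            np.hypot(cols - roi.center[0], rows - roi.center[1]) * px <= roi.radius_um
        )

    bleach_m, ref_m = _mask(rois["bleach"]), _mask(rois["reference"])
    rng = np.random.default_rng(spec.seed)
    frames = []
    for i in range(spec.n_frames):
        fade = (1 - spec.acquisition_bleach_rate) ** i
        signal = np.zeros((nrow, ncol))
        signal[bleach_m] = spec.bleach_signal(i)
        signal[ref_m] = spec.prebleach_intensity
        frame = spec.background_level + fade * signal
        if spec.noise_sd > 0:
            frame = np.clip(
                frame + rng.normal(0, spec.noise_sd, size=(nrow, ncol)), 0, None
            )
        frames.append(PixelImage(values=frame, pixel_size_um=px))
    return frames, rois


# ---------------------------------------------------------------------------
# Sequence and hit-table fixtures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SequenceFixtureSpec:
    """Random protein sequences with non-overlapping planted IWN motifs."""

    n_sequences: int
    length: int
    planted_motifs_per_sequence: int
    alphabet_frequencies: dict[str, float] = field(
        default_factory=lambda: {aa: 1 / 20 for aa in AMINO_ACIDS}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.planted_motifs_per_sequence < 0 or self.n_sequences < 0:
            raise ValueError("counts must be >= 0")
        # non-overlapping 4-mers need at least 4 residues each
        if self.length < 4 * self.planted_motifs_per_sequence:
            raise ValueError(
                f"length {self.length} too short for "
                f"{self.planted_motifs_per_sequence} non-overlapping 4-residue motifs"
            )


def generate_sequence_fixtures(
    spec: SequenceFixtureSpec,
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Generate FASTA-ready records plus a table of planted motif positions.

    Every planted position holds a 4-mer matching the IWN pattern
    (I/L/V, W, two hydrophilic residues); positions are 1-based.  Background
    residues are drawn from ``alphabet_frequencies`` and may create additional
    chance matches; the table records only the planted ones.
    """
    rng = np.random.default_rng(spec.seed)
    letters = sorted(spec.alphabet_frequencies)
    probs = np.array([spec.alphabet_frequencies[a] for a in letters], dtype=float)
    probs = probs / probs.sum()
    hydro = sorted(DEFAULT_HYDROPHILIC)

    records: list[SequenceRecord] = []
    planted_rows = []
    for i in range(spec.n_sequences):
        residues = list(rng.choice(letters, size=spec.length, p=probs))
        starts = _sample_nonoverlapping_starts(
            rng, spec.length, spec.planted_motifs_per_sequence
        )
        ident = f"seq_{i:04d}"
        for s in starts:
            motif = (
                str(rng.choice(list("ILV")))
                + "W"
                + str(rng.choice(hydro))
                + str(rng.choice(hydro))
            )
            residues[s : s + 4] = list(motif)
            planted_rows.append(
                {"identifier": ident, "position": s + 1, "window": motif}
            )
        records.append(SequenceRecord(identifier=ident, residues="".join(residues)))
    table = pd.DataFrame(planted_rows, columns=["identifier", "position", "window"])
    return records, table


def _sample_nonoverlapping_starts(
    rng: np.random.Generator, length: int, count: int
) -> list[int]:
    """Sample 0-based start positions for non-overlapping 4-mers."""
    if count == 0:
        return []
    # place motifs into `count` slots chosen among length - 3*count positions,
    # then re-expand: classic stars-and-bars construction, exact and unbiased
    reduced = rng.choice(length - 3 * count, size=count, replace=False)
    reduced.sort()
    return [int(p + 3 * k) for k, p in enumerate(reduced)]


def generate_blast_table(
    n_rows: int, fraction_passing: float, seed: int
) -> tuple[pd.DataFrame, int]:
    """Build a BLAST-style hit table with an exact planted pass count.

    Exactly ``round(n_rows * fraction_passing)`` rows strictly satisfy both
    filter conditions (coverage > 40, e-value < 1e-3); every other row
    strictly fails at least one.  Returns the shuffled table and the count.
    """
    if not 0 <= fraction_passing <= 1:
        raise ValueError("fraction_passing must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_pass = int(round(n_rows * fraction_passing))
    taxa = ["Metazoa", "Viridiplantae", "Amoebozoa", "Choanoflagellata", "Porifera"]

    rows = []
    for i in range(n_rows):
        if i < n_pass:
            coverage = rng.uniform(40.0, 100.0)
            coverage = max(coverage, np.nextafter(40.0, 100.0))
            evalue = 10.0 ** rng.uniform(-180.0, -3.5)
        else:
            mode = rng.integers(3)
            coverage = (
                rng.uniform(0.0, 40.0) if mode in (0, 2) else rng.uniform(40.5, 100.0)
            )
            evalue = (
                10.0 ** rng.uniform(-2.9, 1.0)
                if mode in (1, 2)
                else 10.0 ** rng.uniform(-180.0, -3.5)
            )
        rows.append(
            {
                "query_id": "query_0001",
                "subject_id": f"subject_{i:04d}",
                "query_coverage_percent": float(coverage),
                "evalue": float(evalue),
                "taxon": taxa[int(rng.integers(len(taxa)))],
            }
        )
    table = pd.DataFrame(rows).iloc[rng.permutation(n_rows)].reset_index(drop=True)
    return table, n_pass
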