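"""Synthetic GPRA promoter libraries with planted regulatory logic.

Emulates the random-promoter reporter assay at desk scale: each library member
is a fixed 17-nt 5' flank, an i.i.d. random insert (80 nt by default), and a
fixed 13-nt 3' flank.  Ground-truth (latent) expression is an additive model:

    latent = baseline + sum(planted motif effects)
             + sum(interaction effects for co-planted pairs)
             + gc_coeff * GC-fraction(insert)

The observed value emulates the flow-sorting readout: ``cells_per_promoter``
cell-level values ``latent + Normal(0, cell_noise_sd)`` are assigned to one of
``n_bins`` equal-width expression bins spanning ``bin_range`` (values clipped),
and the observed expression is the mean bin index (0-based), i.e. the weighted
mean expression bin.  More cells per promoter means a more precise readout,
mirroring the shallow training versus deep test sequencing of the real assay.

The noise model is Gaussian for simplicity; sequencing depth, PCR bias and
plasmid copy number are deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data import BASES, FLANK3_LEN, FLANK5_LEN, PromoterRecord, SEQ_LEN

DEFAULT_FLANK5 = "TGCATTTTTTTCACATC"   # arbitrary fixed 17-nt 5' flank
DEFAULT_FLANK3 = "GGTTACGGCTGTT"       # arbitrary fixed 13-nt 3' flank

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MotifSpec:
    """A plantable motif: PWM (rows A,C,G,T), latent effect and plant rate."""
    name: str
    pwm: np.ndarray
    effect: float
    plant_prob: float = 0.5

    def __post_init__(self) -> None:
        self.pwm = np.asarray(self.pwm, dtype=float)
        if self.pwm.ndim != 2 or self.pwm.shape[0] != 4:
            raise ValueError(f"motif {self.name}: PWM must be 4 x w")
        if self.pwm.shape[1] < 4:
            raise ValueError(f"motif {self.name}: PWM width must be >= 4")
        if not np.allclose(self.pwm.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError(f"motif {self.name}: PWM columns must sum to 1")
        if not 0.0 <= self.plant_prob <= 1.0:
            raise ValueError(f"motif {self.name}: plant_prob outside [0, 1]")

    @property
    def width(self) -> int:
        return self.pwm.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.pwm.argmax(axis=0))


def motif_from_consensus(name: str, consensus: str, effect: float,
                         plant_prob: float = 0.5,
                         consensus_prob: float = 1.0) -> MotifSpec:
    """Build a MotifSpec whose PWM puts ``consensus_prob`` on the consensus
    base at every column (remaining mass spread over the other bases)."""
    w = len(consensus)
    off = (1.0 - consensus_prob) / 3.0
    pwm = np.full((4, w), off)
    for j, base in enumerate(consensus.upper()):
        pwm[BASES.index(base), j] = consensus_prob
    return MotifSpec(name, pwm, effect, plant_prob)


@dataclass
class InteractionSpec:
    """Extra latent shift when both named motifs are planted in one insert."""
    motif_a: str
    motif_b: str
    effect: float

    def __post_init__(self) -> None:
        if self.motif_a == self.motif_b:
            raise ValueError("interaction requires two distinct motifs")


@dataclass
class LibrarySpec:
    n: int = 1000
    insert_len: int = 80
    flank5: str = DEFAULT_FLANK5
    flank3: str = DEFAULT_FLANK3
    baseline: float = 0.0
    gc_coeff: float = 0.0
    motifs: list[MotifSpec] = field(default_factory=list)
    interactions: list[InteractionSpec] = field(default_factory=list)
    n_bins: int = 18
    cells_per_promoter: int = 100
    cell_noise_sd: float = 1.0
    bin_range: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.flank5) != FLANK5_LEN or len(self.flank3) != FLANK3_LEN:
            raise ValueError(
                f"flanks must be {FLANK5_LEN} and {FLANK3_LEN} nt")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.cells_per_promoter < 1:
            raise ValueError("cells_per_promoter must be >= 1")
        if self.bin_range is not None and self.bin_range[0] >= self.bin_range[1]:
            raise ValueError("bin_range low must be < high")
        names = [m.name for m in self.motifs]
        if len(set(names)) != len(names):
            raise ValueError("motif names must be unique")
        for ia in self.interactions:
            for nm in (ia.motif_a, ia.motif_b):
                if nm not in names:
                    raise ValueError(f"interaction references unknown motif {nm}")

    @property
    def total_len(self) -> int:
        return FLANK5_LEN + self.insert_len + FLANK3_LEN


@dataclass
class SimRecord:
    sequence: str
    latent: float
    observed: float
    planted: list[tuple[str, int, str]]  # (motif name, 1-based start, strand)

    def to_promoter_record(self) -> PromoterRecord:
        return PromoterRecord(self.sequence, self.observed)


# --------------------------------------------------------------------------- #

def gc_fraction(seq: str) -> float:
    acgt = sum(seq.count(b) for b in BASES)
    if acgt == 0:
        raise ValueError("sequence has no called bases")
    return (seq.count("G") + seq.count("C")) / acgt


def latent_expression(sequence: str, spec: LibrarySpec,
                      planted: list[tuple[str, int, str]]) -> float:
    """Noise-free expression of one promoter under the additive ground truth."""
    if len(sequence) != spec.total_len:
        raise ValueError(
            f"sequence length {len(sequence)} != {spec.total_len}")
    effects = {m.name: m.effect for m in spec.motifs}
    present = {name for name, _, _ in planted}
    value = spec.baseline
    for name in present:
        value += effects[name]
    for ia in spec.interactions:
        if ia.motif_a in present and ia.motif_b in present:
            value += ia.effect
    if spec.gc_coeff:
        insert = sequence[FLANK5_LEN:FLANK5_LEN + spec.insert_len]
        value += spec.gc_coeff * gc_fraction(insert)
    return float(value)


def resolve_bin_range(spec: LibrarySpec,
                      n_draws: int = 10_000) -> tuple[float, float]:
    """The bin grid used for the readout.  When the spec leaves it open, span
    mean +/- 2 sd of the latent distribution, estimated from ``n_draws``
    simulated latents (deterministic given spec.seed)."""
    if spec.bin_range is not None:
        return spec.bin_range
    probe = replace(spec, n=n_draws, bin_range=(0.0, 1.0), cell_noise_sd=0.0,
                    cells_per_promoter=1,
                    seed=int(np.random.SeedSequence(
                        [spec.seed, 0xB1A5]).generate_state(1)[0] % (2 ** 31)))
    latents = np.array([r.latent for r in generate_library(probe)])
    mu, sd = latents.mean(), latents.std()
    if sd == 0:
        sd = 1.0
    return (float(mu - 2 * sd), float(mu + 2 * sd))


def _binned(latent: float, spec: LibrarySpec, rng: np.random.Generator,
            bin_range: tuple[float, float]) -> float:
    lo, hi = bin_range
    if lo >= hi:
        raise ValueError("degenerate bin_range: low >= high")
    cells = latent + rng.normal(0.0, spec.cell_noise_sd,
                                size=spec.cells_per_promoter)
    width = (hi - lo) / spec.n_bins
    idx = np.clip(np.floor((cells - lo) / width), 0, spec.n_bins - 1)
    return float(idx.mean())


def binned_readout(latent: float, spec: LibrarySpec, seed: int) -> float:
    """Weighted-mean expression bin (0-based) of one promoter's cells."""
    rng = np.random.default_rng(seed)
    return _binned(latent, spec, rng, resolve_bin_range(spec))


def generate_library(spec: LibrarySpec) -> list[SimRecord]:
    """Draw a library of ``spec.n`` promoters with planted motifs."""
    for m in spec.motifs:
        if m.width > spec.insert_len:
            raise ValueError(
                f"motif {m.name} (width {m.width}) does not fit in the "
                f"{spec.insert_len}-nt insert")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x5E0]))
    bin_range = resolve_bin_range(spec)
    cums = {m.name: m.pwm.T.cumsum(axis=1) for m in spec.motifs}
    records: list[SimRecord] = []
    for _ in range(spec.n):
        insert = rng.integers(0, 4, size=spec.insert_len)
        planted: list[tuple[str, int, str]] = []
        occupied: list[tuple[int, int]] = []
        for m in spec.motifs:
            if rng.random() >= m.plant_prob:
                continue
            w = m.width
            for attempt in range(100):
                off = int(rng.integers(0, spec.insert_len - w + 1))
                if all(off + w <= s or off >= e for s, e in occupied):
                    break
            else:
                raise RuntimeError(
                    f"could not place motif {m.name} without overlap "
                    f"after 100 attempts")
            occupied.append((off, off + w))
            # sample a site from the PWM columns, then orient by strand
            u = rng.random(w)
            site_idx = np.array([np.searchsorted(cums[m.name][j], u[j])
                                 for j in range(w)])
            site = "".join(BASES[i] for i in site_idx)
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                site = reverse_complement(site)
            for j, base in enumerate(site):
                insert[off + j] = BASES.index(base)
            planted.append((m.name, FLANK5_LEN + off + 1, strand))
        seq = (spec.flank5
               + "".join(BASES[i] for i in insert)
               + spec.flank3)
        latent = latent_expression(seq, spec, planted)
        observed = _binned(latent, spec, rng, bin_range)
        records.append(SimRecord(seq, latent, observed, planted))
    return records


# --------------------------------------------------------------------------- #

def write_library(records: list[SimRecord], table_path,
                  sidecar_path=None) -> None:
    """Write the two-column TSV consumed by the data reader, plus an optional
    ground-truth sidecar (sequence, latent, name:start:strand triples)."""
    with open(table_path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f"{rec.sequence}\t{rec.observed!r}\n")
    if sidecar_path is not None:
        with open(sidecar_path, "w", encoding="utf-8") as fh:
            for rec in records:
                ann = ";".join(f"{n}:{s}:{st}" for n, s, st in rec.planted)
                fh.write(f"{rec.sequence}\t{rec.latent!r}\t{ann}\n")


def read_sidecar(path) -> list[tuple[str, float, list[tuple[str, int, str]]]]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            seq, latent, ann = line.rstrip("\n").split("\t")
            planted = []
            if ann:
                for trip in ann.split(";"):
                    name, start, strand = trip.rsplit(":", 2)
                    planted.append((name, int(start), strand))
            out.append((seq, float(latent), planted))
    return out
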