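"""Forward model of the pool-irradiation survival assay and synthetic data.

The generator replaces the wet-lab chain (synthesis, 266 nm irradiation,
library-prep discrimination, sequencing) with a seeded stochastic model:

* every strand ``tail + octamer + tail`` carries a *hazard* ``h`` — the sum
  of effective dimeric damage yields over all adjacent base pairs touching
  the randomized octamer (a lesion anywhere in that stretch stops the
  polymerase, so the whole insert counts);
* the intact fraction follows two-state linear kinetics in dose with a
  photoreversal channel (lesion converts back on secondary absorption) and
  an irreversible sink, giving the bi-exponential survival seen for poly-T;
* library preparation discriminates damaged strands down to a small
  leak-through probability ``epsilon`` (~10^-3, the observed roughly
  thousand-fold suppression of lesion-carrying strands);
* synthesis/readout bias is a per-octamer log-normal weight, and reads per
  dose level are a multinomial draw of the configured depth.

Dimeric yields of pyrimidine-pyrimidine pairs are quenched by a factor
``(1 - q)`` per immediately adjacent guanine (charge-transfer deactivation).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .sequence_space import (
    BASES,
    CountTable,
    G_DIGIT,
    all_kmers,
    digit_matrix,
    digits_of,
    index_of,
)

_PYR_DIGIT = np.array([False, True, False, True])  # C and T

#: Dimeric damage quantum yields (damages per photon absorbed in the dimer)
#: for the four dimer types the assay resolves; all other dimers sit below
#: the ~0.5e-3 sensitivity floor and are set to zero.
CANONICAL_YIELDS: dict[str, float] = {
    "TT": 0.021,
    "CT": 0.011,
    "TC": 0.011,
    "CC": 0.006,
    "AA": 0.0019,
}


@dataclass
class PhotophysicsParams:
    """Ground-truth photophysics of the forward model.

    Attributes
    ----------
    phi:
        4x4 array of directional dimeric damage quantum yields, indexed by
        base digits (A=0, C=1, G=2, T=3): ``phi[x, y]`` is the yield of the
        ordered dimer XY in damages per photon absorbed in the dimer.
    q:
        Charge-transfer quench factor in [0, 1]; each guanine immediately
        adjacent to a pyrimidine-pyrimidine dimer multiplies that dimer's
        yield by ``1 - q``.
    rho:
        Photoreversal coefficient of the lesion state (per photon/base).
    sigma:
        Irreversible secondary-decay coefficient of the lesion state
        (per photon/base).
    epsilon:
        Leak-through probability that a damaged strand is still read.
    """

    phi: np.ndarray
    q: float = 0.5
    rho: float = 0.004
    sigma: float = 0.001
    epsilon: float = 1e-3

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        if self.phi.shape != (4, 4):
            raise ValueError("phi must be a 4x4 array of dimer yields")
        if np.any(self.phi < 0):
            raise ValueError("dimer yields must be non-negative")
        if not 0.0 <= self.q <= 1.0:
            raise ValueError("quench factor q must be in [0, 1]")
        if self.rho < 0 or self.sigma < 0:
            raise ValueError("rho and sigma must be non-negative")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("leak-through epsilon must be in [0, 1]")

    @classmethod
    def from_yields(cls, yields: dict[str, float], **kwargs) -> "PhotophysicsParams":
        """Build from a ``{"XY": value}`` mapping; unlisted dimers are zero."""
        phi = np.zeros((4, 4))
        for xy, value in yields.items():
            phi[index_of(xy[0]), index_of(xy[1])] = value
        return cls(phi=phi, **kwargs)

    @classmethod
    def default(cls, **kwargs) -> "PhotophysicsParams":
        """Canonical yield table (TT 0.021, CT/TC 0.011, CC 0.006, AA 0.0019)."""
        return cls.from_yields(CANONICAL_YIELDS, **kwargs)

    def yield_of(self, dimer: str) -> float:
        return float(self.phi[index_of(dimer[0]), index_of(dimer[1])])

    def yields_dict(self) -> dict[str, float]:
        return {
            x + y: float(self.phi[i, j])
            for i, x in enumerate(BASES)
            for j, y in enumerate(BASES)
        }


@dataclass
class PoolSpec:
    """Composition, bias and sequencing depth of the synthetic pool."""

    tail: str = "ACAC"
    random_length: int = 8
    bias_sigma: float = 1.0  # log-normal spread; 1.0 gives max/mean ~ 40 at 4**8
    depth: int = 1_000_000  # reads per dose level

    def __post_init__(self) -> None:
        if any(b not in BASES for b in self.tail):
            raise ValueError("tail must be over ACGT")
        if not 1 <= self.random_length <= 8:
            raise ValueError("random_length must be in 1..8")
        if self.bias_sigma < 0:
            raise ValueError("bias_sigma must be non-negative")
        if self.depth < 1:
            raise ValueError("depth must be at least 1 read per dose")


@dataclass
class DoseSchedule:
    """Absorbed photons per base at each extraction, ascending from 0."""

    doses: np.ndarray

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        if self.doses.size == 0 or self.doses[0] != 0.0:
            raise ValueError("dose schedule must start at 0")
        if np.any(np.diff(self.doses) <= 0):
            raise ValueError("doses must be strictly increasing")

    @classmethod
    def log_spaced(
        cls, n: int = 16, d_max: float = 500.0, d_min: float = 2.0
    ) -> "DoseSchedule":
        """Zero plus ``n - 1`` log-spaced doses from d_min to d_max.

        Dense sampling at low dose pins the initial slopes of fast-decaying
        classes, mirroring the many early extractions of the experiment.
        """
        if n < 2:
            raise ValueError("need at least two dose levels")
        body = np.geomspace(d_min, d_max, n - 1)
        return cls(doses=np.concatenate([[0.0], body]))

    def __len__(self) -> int:
        return self.doses.size


def _pair_yield(strand: np.ndarray, p: int, params: PhotophysicsParams) -> float:
    """Effective yield of the dimer at positions (p, p+1) of a digit strand."""
    x, y = strand[p], strand[p + 1]
    base = params.phi[x, y]
    if base == 0.0 or not (_PYR_DIGIT[x] and _PYR_DIGIT[y]):
        return float(base)
    g = 0
    if p - 1 >= 0 and strand[p - 1] == G_DIGIT:
        g += 1
    if p + 2 < strand.size and strand[p + 2] == G_DIGIT:
        g += 1
    return float(base * (1.0 - params.q) ** g)


def strand_hazard(octamer: str, tail: str, params: PhotophysicsParams) -> float:
    """Total damage hazard (per photon/base) of one tailed strand.

    Sums the effective dimeric yield over every adjacent base pair of
    ``tail + octamer + tail`` that touches at least one octamer base: a
    lesion at the tail-octamer junction also blocks readout, which is why
    an i-mer with randomized flanks sees i+1 damageable pairs.
    """
    strand = digits_of(tail + octamer + tail)
    start, stop = len(tail), len(tail) + len(octamer)  # octamer as [start, stop)
    h = 0.0
    for p in range(start - 1, stop):
        h += _pair_yield(strand, p, params)
    return h


def pool_hazards(
    params: PhotophysicsParams, tail: str = "ACAC", random_length: int = 8
) -> np.ndarray:
    """Vectorized :func:`strand_hazard` over all 4**random_length octamers."""
    L = random_length
    n = 4**L
    t = digits_of(tail)
    strand = np.empty((n, 2 * t.size + L), dtype=np.int8)
    strand[:, : t.size] = t
    strand[:, t.size : t.size + L] = digit_matrix(L)
    strand[:, t.size + L :] = t
    width = strand.shape[1]
    one_minus_q = 1.0 - params.q
    H = np.zeros(n)
    for p in range(t.size - 1, t.size + L):
        x = strand[:, p]
        y = strand[:, p + 1]
        yld = params.phi[x, y]
        pyr = _PYR_DIGIT[x] & _PYR_DIGIT[y]
        g = np.zeros(n, dtype=np.int8)
        if p - 1 >= 0:
            g += strand[:, p - 1] == G_DIGIT
        if p + 2 < width:
            g += strand[:, p + 2] == G_DIGIT
        H += np.where(pyr, yld * one_minus_q**g, yld)
    return H


def intact_fraction(h, rho: float, sigma: float, D) -> np.ndarray:
    """Closed-form intact fraction I(D) of the two-state lesion kinetics.

    dI/dD = -h I + rho L,  dL/dD = h I - (rho + sigma) L,  I(0)=1, L(0)=0.

    Solved by eigen-decomposition of the 2x2 rate matrix; bi-exponential in
    D, reducing to ``exp(-h D)`` when ``rho == 0``.  ``h`` and ``D``
    broadcast against each other.
    """
    h = np.asarray(h, dtype=float)
    D = np.asarray(D, dtype=float)
    if np.any(h < 0) or rho < 0 or sigma < 0:
        raise ValueError("rates must be non-negative")
    if np.any(D < 0):
        raise ValueError("doses must be non-negative")
    s = h + rho + sigma  # -trace
    det = h * sigma
    disc = np.sqrt(np.maximum(s * s - 4.0 * det, 0.0))
    lam1 = 0.5 * (-s + disc)
    lam2 = 0.5 * (-s - disc)
    h_b, _ = np.broadcast_arrays(h, lam1)
    lam1 = np.broadcast_to(lam1, h_b.shape)
    lam2 = np.broadcast_to(lam2, h_b.shape)
    degenerate = disc < 1e-14 * np.maximum(s, 1.0)
    degenerate = np.broadcast_to(degenerate, h_b.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        A = (-h_b - lam2) / (lam1 - lam2)
    A = np.where(degenerate, 1.0, A)
    out = A * np.exp(lam1 * D) + (1.0 - A) * np.exp(lam2 * D)
    if np.any(degenerate):
        lam = 0.5 * (lam1 + lam2)
        series = (1.0 + (-h_b - lam) * D) * np.exp(lam * D)
        out = np.where(degenerate, series, out)
    return np.clip(out, 0.0, 1.0)


def sample_bias(pool: PoolSpec, rng: np.random.Generator) -> np.ndarray:
    """Per-octamer synthesis/readout weights (log-normal, mean-1 scale)."""
    return rng.lognormal(mean=0.0, sigma=pool.bias_sigma, size=4**pool.random_length)


def simulate_counts(
    pool: PoolSpec,
    params: PhotophysicsParams,
    schedule: DoseSchedule,
    seed: int,
    bias: np.ndarray | None = None,
) -> CountTable:
    """Sample a full dose-series octamer count table.

    Per dose level j, read probabilities are proportional to
    ``b_i * (I_i(D_j) + epsilon * (1 - I_i(D_j)))`` and counts are one
    multinomial draw of ``pool.depth`` reads.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    if bias is None:
        bias = sample_bias(pool, rng)
    bias = np.asarray(bias, dtype=float)
    if bias.shape != (4**pool.random_length,) or np.any(bias <= 0):
        raise ValueError("bias must be positive with one weight per octamer")
    H = pool_hazards(params, pool.tail, pool.random_length)
    I = intact_fraction(H[:, None], params.rho, params.sigma, schedule.doses[None, :])
    weights = bias[:, None] * (I + params.epsilon * (1.0 - I))
    counts = np.empty((4**pool.random_length, len(schedule)), dtype=np.int64)
    for j in range(len(schedule)):
        p = weights[:, j] / weights[:, j].sum()
        counts[:, j] = rng.multinomial(pool.depth, p)
    return CountTable(
        counts=counts, doses=schedule.doses.copy(), k=pool.random_length, tail=pool.tail
    )


def emit_fastq(
    table: CountTable,
    directory,
    prefix: str = "pool",
    quality: int = 40,
    low_quality_rate: float = 0.0,
    low_quality: int = 2,
    seed: int = 0,
) -> list[tuple[float, Path]]:
    """Write one FASTQ file (Phred+33) per dose level, one read per count.

    Each read is ``tail + octamer + tail`` at constant quality; with
    ``low_quality_rate > 0`` individual bases are independently demoted to
    ``low_quality`` (for exercising downstream quality filtering).

    Returns ``[(dose, path), ...]`` in dose order.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    tail = table.tail
    kmers = all_kmers(table.k)
    full = [tail + s + tail for s in kmers]
    read_len = len(full[0])
    qual_hi = chr(33 + quality)
    qual_lo = chr(33 + low_quality)
    flat_qual = qual_hi * read_len
    out: list[tuple[float, Path]] = []
    for j, dose in enumerate(table.doses):
        path = directory / f"{prefix}_d{j:02d}.fastq"
        reps = np.repeat(np.arange(len(kmers)), table.counts[:, j])
        with open(path, "w") as fh:
            chunk: list[str] = []
            for r, i in enumerate(reps):
                if low_quality_rate > 0.0:
                    bad = rng.random(read_len) < low_quality_rate
                    qual = "".join(
                        qual_lo if b else qual_hi for b in bad
                    ) if bad.any() else flat_qual
                else:
                    qual = flat_qual
                chunk.append(f"@{prefix}_j{j}_r{r}\n{full[i]}\n+\n{qual}\n")
                if len(chunk) >= 100_000:
                    fh.write("".join(chunk))
                    chunk.clear()
            fh.write("".join(chunk))
        out.append((float(dose), path))
    return out
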