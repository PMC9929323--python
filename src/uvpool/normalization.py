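"""Bias-cancelling normalization of count tables to relative frequencies.

Raw per-class frequencies carry strong synthesis/readout bias.  The double
ratio

    r_i(D_j) = [n_i(D_j) / n_ref(D_j)] * [n_ref(0) / n_i(0)] * exp(-mu_ref D_j)

cancels any per-class multiplicative bias exactly, anchors every class at
r_i(0) = 1, and restores the slow decay of the poly-G reference class via
the ``exp(-mu_ref D)`` factor (``mu_ref`` is the reference's own local
damage coefficient, which the double ratio would otherwise divide out).

``mu_ref`` can be supplied as a fixed value or estimated self-consistently:
normalize, fit all tetramer classes, invert the dimer model, predict the
reference hazard from the fitted yields, and iterate to the fixed point.

Standard errors come from Poisson counting statistics, combined to first
order across the four counts entering the double ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sequence_space import CountTable, all_kmers, index_of, marginalize


@dataclass
class RelFreqTable:
    """Relative frequencies r_i(D_j) per class per dose, with errors.

    ``valid`` flags classes with a nonzero zero-dose count; rows of excluded
    classes are NaN.
    """

    relfreq: np.ndarray
    stderr: np.ndarray
    doses: np.ndarray
    k: int
    reference: str
    mu_ref: float
    valid: np.ndarray

    @property
    def sequences(self) -> tuple[str, ...]:
        return all_kmers(self.k)

    def series(self, sequence: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(doses, relfreq, stderr) for one class."""
        i = index_of(sequence)
        if not self.valid[i]:
            raise ValueError(f"class {sequence} was excluded (zero count at D=0)")
        return self.doses, self.relfreq[i], self.stderr[i]

    def to_tsv(self, path) -> None:
        seqs = self.sequences
        rows = []
        for i in np.flatnonzero(self.valid):
            for j, d in enumerate(self.doses):
                rows.append((seqs[i], d, self.relfreq[i, j], self.stderr[i, j]))
        df = pd.DataFrame(rows, columns=["sequence", "dose", "relfreq", "stderr"])
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path, reference: str | None = None, mu_ref: float = float("nan")):
        df = pd.read_csv(path, sep="\t")
        k = len(str(df["sequence"].iloc[0]))
        doses = np.array(sorted(df["dose"].unique()), dtype=float)
        n = 4**k
        relfreq = np.full((n, doses.size), np.nan)
        stderr = np.full((n, doses.size), np.nan)
        valid = np.zeros(n, dtype=bool)
        dose_pos = {d: j for j, d in enumerate(doses)}
        for seq, grp in df.groupby("sequence"):
            i = index_of(str(seq))
            valid[i] = True
            for _, row in grp.iterrows():
                j = dose_pos[float(row["dose"])]
                relfreq[i, j] = row["relfreq"]
                stderr[i, j] = row["stderr"]
        return cls(
            relfreq=relfreq,
            stderr=stderr,
            doses=doses,
            k=k,
            reference=reference or "G" * k,
            mu_ref=mu_ref,
            valid=valid,
        )


def relative_frequencies(
    table: CountTable, reference: str | None = None, mu_ref: float = 0.0
) -> RelFreqTable:
    """Double-ratio normalization of a count table against a reference class.

    The reference defaults to the poly-G class of the table's k.  Classes
    with a zero count in the unirradiated sample are flagged invalid; a zero
    reference count at any dose is an error.
    """
    reference = reference or "G" * table.k
    if len(reference) != table.k:
        raise ValueError(
            f"reference {reference!r} has length {len(reference)}, table k={table.k}"
        )
    ri = index_of(reference)
    n = table.counts.astype(float)
    nref = n[ri]
    if np.any(nref == 0):
        bad = table.doses[nref == 0]
        raise ValueError(f"reference class {reference} has zero counts at doses {bad}")
    n0 = n[:, 0]
    valid = n0 > 0
    restore = np.exp(-mu_ref * table.doses)[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (n / nref[None, :]) * (nref[0] / n0)[:, None] * restore
    r[~valid] = np.nan
    # first-order Poisson variance of the double ratio; counts floored at one
    # pseudo-count so vanished classes keep finite weights
    nf = np.maximum(n, 1.0)
    var_rel = (
        1.0 / nf
        + 1.0 / nref[None, :]
        + (1.0 / np.maximum(n0, 1.0) + 1.0 / nref[0])[:, None]
    )
    # scale errors with at least the one-pseudo-count frequency floor
    r_floor = (1.0 / nref[None, :]) * (nref[0] / np.maximum(n0, 1.0))[:, None] * restore
    stderr = np.maximum(r, r_floor) * np.sqrt(var_rel)
    stderr[~valid] = np.nan
    return RelFreqTable(
        relfreq=r,
        stderr=stderr,
        doses=table.doses.copy(),
        k=table.k,
        reference=reference,
        mu_ref=mu_ref,
        valid=valid,
    )


@dataclass
class MuRefEstimate:
    """Fixed point of the self-consistent reference-decay estimation."""

    mu_ref: float
    trace: list[float]
    n_iter: int
    yields: object  # DimerYieldSet of the final iteration

    @property
    def q(self) -> float:
        return self.yields.q

    @property
    def phi(self) -> np.ndarray:
        return self.yields.phi


def estimate_mu_ref(
    table: CountTable,
    k: int = 4,
    tol: float = 1e-6,
    max_iter: int = 50,
    tie_pairs: bool = True,
) -> MuRefEstimate:
    """Self-consistent reference damage coefficient from the data itself.

    Iterates: normalize the marginalized k-mer table with the current
    ``mu_ref``, fit the complete dimer-damage model to all class decay
    curves (:func:`~uvpool.dimer_inversion.fit_pool_model`, with the
    unirradiated octamer counts as flank-mixture weights), and set
    ``mu_ref`` to the reference class's own nearest-neighbor hazard
    predicted from the fitted yields.  Converges when ``mu_ref`` changes by
    less than ``tol``.
    """
    from .dimer_inversion import _pool_model_x0, fit_pool_model, predicted_hazard

    sub = marginalize(table, k)
    reference = "G" * k
    bias_weights = table.counts[:, 0].astype(float)
    mu_ref = 0.0
    trace: list[float] = []
    x0 = None
    for it in range(1, max_iter + 1):
        rft = relative_frequencies(sub, reference, mu_ref)
        yields = fit_pool_model(
            rft,
            counts=sub,
            parent_length=table.k,
            tail=table.tail,
            tie_pairs=tie_pairs,
            weights=bias_weights,
            x0=x0,
        )
        x0 = _pool_model_x0(yields)
        new = predicted_hazard(
            reference,
            yields.phi,
            yields.q,
            context="nearest",
            parent_length=table.k,
            tail=table.tail,
        )
        trace.append(new)
        if abs(new - mu_ref) < tol:
            return MuRefEstimate(mu_ref=new, trace=trace, n_iter=it, yields=yields)
        mu_ref = new
    raise RuntimeError(
        f"mu_ref did not converge in {max_iter} iterations; trace={trace}"
    )
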