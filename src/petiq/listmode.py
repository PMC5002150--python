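"""Reduced-dose simulation by list-mode event discarding.

A lower injected dose is emulated by retaining each detected event
independently with probability equal to the target count fraction
(binomial thinning); true and random events are thinned by the same
procedure.  An alternative bootstrap resampler draws events with
replacement.  Multi-realization ensembles are organized over an ordered
schedule of count fractions with reproducible per-realization sub-seeds.

Note that realizations at one fraction are thinned from the same parent
stream and therefore share its noise: two realizations at fraction f are
correlated with coefficient ~f.  They are effectively independent only
when f is small, which is the regime of the count-response analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantom import EventStream

__all__ = [
    "PAPER_FRACTIONS",
    "EnsembleSpec",
    "FractionSchedule",
    "bootstrap_stream",
    "make_ensembles",
    "sub_seed",
    "thin_stream",
]

#: The ten predefined retention fractions of the original net true counts.
PAPER_FRACTIONS: tuple[float, ...] = (
    5e-1, 2.5e-1, 1.25e-1, 6.25e-2, 3.33e-2, 1.67e-2, 5e-3, 3.33e-3, 1.67e-3, 5e-4,
)

DEFAULT_N_REALIZATIONS = 10


@dataclass(frozen=True)
class FractionSchedule:
    """Ordered retention fractions and the number of realizations at each."""

    fractions: tuple[float, ...] = PAPER_FRACTIONS
    n_realizations: int = DEFAULT_N_REALIZATIONS

    def __post_init__(self) -> None:
        fr = tuple(float(f) for f in self.fractions)
        object.__setattr__(self, "fractions", fr)
        if len(fr) == 0:
            raise ValueError("schedule must contain at least one fraction")
        if any(not 0.0 < f <= 1.0 for f in fr):
            raise ValueError("fractions must lie in (0, 1]")
        if any(fr[i + 1] >= fr[i] for i in range(len(fr) - 1)):
            raise ValueError("fractions must be strictly decreasing")
        if self.n_realizations < 1:
            raise ValueError("n_realizations must be >= 1")


@dataclass
class EnsembleSpec:
    """All realization streams of one subject at one count fraction."""

    subject_id: str
    fraction: float
    streams: list[EventStream]
    seeds: list[int] = field(default_factory=list)


def sub_seed(master_seed: int, fraction_index: int, realization_index: int) -> int:
    """Deterministic per-realization seed.

    Derived by hashing the tuple (master_seed, fraction index, realization
    index) through ``numpy.random.SeedSequence``, so any single realization
    can be regenerated in isolation.  The result fits in 32 bits.
    """
    ss = np.random.SeedSequence([int(master_seed), int(fraction_index), int(realization_index)])
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def _child_provenance(stream: EventStream, fraction: float, seed: int, method: str) -> dict:
    prov = dict(stream.provenance)
    prov.update({"fraction": float(prov.get("fraction", 1.0)) * float(fraction),
                 "seed": int(seed), "method": method})
    return prov


def thin_stream(stream: EventStream, fraction: float, seed: int) -> EventStream:
    """Retain each event independently with probability ``fraction``.

    Trues and randoms are subjected to the same Bernoulli procedure, so
    retained counts fluctuate binomially around ``fraction * n_events``.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    rng = np.random.default_rng(seed)
    keep = rng.random(len(stream)) < fraction
    return EventStream(
        bin_index=stream.bin_index[keep],
        is_random=stream.is_random[keep],
        domain=stream.domain,
        provenance=_child_provenance(stream, fraction, seed, "thin"),
    )


def bootstrap_stream(stream: EventStream, fraction: float, seed: int) -> EventStream:
    """Draw ``round(fraction * n_events)`` events with replacement."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    rng = np.random.default_rng(seed)
    k = int(round(fraction * len(stream)))
    idx = rng.integers(0, len(stream), size=k) if k > 0 else np.empty(0, dtype=np.int64)
    return EventStream(
        bin_index=stream.bin_index[idx],
        is_random=stream.is_random[idx],
        domain=stream.domain,
        provenance=_child_provenance(stream, fraction, seed, "bootstrap"),
    )


def make_ensembles(stream: EventStream, schedule: FractionSchedule, master_seed: int,
                   method: str = "thin") -> list[EnsembleSpec]:
    """Generate the realization ensembles for every fraction of a schedule."""
    if len(stream) == 0:
        raise ValueError("parent stream is empty")
    if method not in ("thin", "bootstrap"):
        raise ValueError(f"unknown method {method!r}")
    resample = thin_stream if method == "thin" else bootstrap_stream
    subject = str(stream.provenance.get("subject", "subject"))
    out = []
    for fi, fraction in enumerate(schedule.fractions):
        seeds, streams = [], []
        for ri in range(schedule.n_realizations):
            s = sub_seed(master_seed, fi, ri)
            child = resample(stream, fraction, s)
            child.provenance["realization"] = ri
            seeds.append(s)
            streams.append(child)
        out.append(EnsembleSpec(subject_id=subject, fraction=float(fraction),
                                streams=streams, seeds=seeds))
    return out
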