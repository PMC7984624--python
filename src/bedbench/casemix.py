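"""Case-Mix Index (CMI) and Performance Index (PI) against a pooled benchmark.

Both indices compare a regional hospital "structure" with a reference profile
pooled over all structures under study (here: all included regions of the
countries analysed).  Writing ``A_j`` for the average length of stay (AvLOS)
of specialty ``j`` and ``s_j`` for a discharge share, the two indices are

    CMI = sum_j A_j^REF * s_j^STR / A_ALL^REF
    PI  = sum_j A_j^STR * s_j^REF / A_ALL^REF

CMI > 1 means the structure's discharge mix is tilted toward specialties
with long reference stays (a more complex case load); PI > 1 means the
structure keeps patients longer than the benchmark would at the reference
mix (lower performance).  ``A_ALL^REF`` is the discharge-weighted mean of
the specialty reference AvLOS, which makes both indices exactly 1 for a
structure identical to the benchmark.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

from .errors import DomainError

__all__ = [
    "SpecialtyStats",
    "Benchmark",
    "Quadrant",
    "CaseMixResult",
    "build_benchmark",
    "compute_cmi",
    "compute_pi",
    "classify_quadrant",
    "pi_cmi_ratio",
]


@dataclass(frozen=True)
class SpecialtyStats:
    """Discharges and average length of stay of one specialty in one structure.

    Specialties are identified by an ICD-10 chapter code as delivered by the
    hospital-discharge tables; any consistent partition of diagnoses works.
    """

    specialty: str
    discharges: float
    avlos: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.discharges) and math.isfinite(self.avlos)):
            raise DomainError(f"specialty {self.specialty!r}: non-finite values")
        if self.discharges < 0 or self.avlos < 0:
            raise DomainError(f"specialty {self.specialty!r}: negative values")


@dataclass(frozen=True)
class Benchmark:
    """Pooled reference profile: per-specialty AvLOS, discharges and shares.

    ``overall_avlos`` is the discharge-weighted mean of ``ref_avlos`` and is
    the normalising constant of both indices.
    """

    specialties: tuple[str, ...]
    ref_avlos: dict[str, float]
    ref_discharges: dict[str, float]
    total_ref_discharges: float = field(init=False)
    ref_share: dict[str, float] = field(init=False)
    overall_avlos: float = field(init=False)

    def __post_init__(self) -> None:
        total = sum(self.ref_discharges[s] for s in self.specialties)
        if total <= 0:
            raise DomainError("benchmark has zero total discharges")
        shares = {s: self.ref_discharges[s] / total for s in self.specialties}
        overall = sum(shares[s] * self.ref_avlos[s] for s in self.specialties)
        object.__setattr__(self, "total_ref_discharges", total)
        object.__setattr__(self, "ref_share", shares)
        object.__setattr__(self, "overall_avlos", overall)


class Quadrant(str, Enum):
    """CMI/PI quadrant of the four-quadrant complexity-performance diagram."""

    GREEN = "GREEN"    # CMI > 1, PI < 1: high complexity, efficiently managed
    YELLOW = "YELLOW"  # CMI <= 1, PI < 1: low complexity, efficiently managed
    ORANGE = "ORANGE"  # CMI > 1, PI >= 1: high complexity, low performance
    RED = "RED"        # CMI <= 1, PI >= 1: low complexity, low performance


@dataclass(frozen=True)
class CaseMixResult:
    """CMI, PI, quadrant and benchmark coverage for one structure."""

    cmi: float
    pi: float
    quadrant: Quadrant
    coverage: float


def build_benchmark(records) -> Benchmark:
    """Pool specialty profiles of many structures into a reference benchmark.

    Parameters
    ----------
    records
        Iterable of objects with a ``specialties`` attribute (a sequence of
        :class:`SpecialtyStats`), e.g. assembled region-year records.

    The reference discharge count of a specialty is the sum over structures;
    the reference AvLOS is the discharge-weighted mean of structure AvLOS.
    """
    disch: dict[str, float] = {}
    days: dict[str, float] = {}
    order: list[str] = []
    for rec in records:
        for st in rec.specialties:
            if st.specialty not in disch:
                disch[st.specialty] = 0.0
                days[st.specialty] = 0.0
                order.append(st.specialty)
            disch[st.specialty] += st.discharges
            days[st.specialty] += st.discharges * st.avlos
    order = [s for s in order if disch[s] > 0]
    if not order or sum(disch[s] for s in order) <= 0:
        raise DomainError("cannot build benchmark: zero pooled discharges")
    avlos = {s: days[s] / disch[s] for s in order}
    return Benchmark(
        specialties=tuple(order),
        ref_avlos={s: avlos[s] for s in order},
        ref_discharges={s: disch[s] for s in order},
    )


def _shared(specialties, benchmark: Benchmark) -> list[SpecialtyStats]:
    bench = set(benchmark.specialties)
    shared = [s for s in specialties if s.specialty in bench and s.discharges > 0]
    if not shared:
        raise DomainError("no specialties shared between structure and benchmark")
    return shared


def coverage_fraction(specialties, benchmark: Benchmark) -> float:
    """Fraction of the structure's discharges in specialties shared with the benchmark."""
    total = sum(s.discharges for s in specialties)
    if total <= 0:
        return 0.0
    bench = set(benchmark.specialties)
    shared = sum(s.discharges for s in specialties if s.specialty in bench)
    return shared / total


def compute_cmi(specialties, benchmark: Benchmark) -> float:
    """Case-Mix Index of a structure's specialty mix against the benchmark.

    Structure discharge shares are renormalised over the specialties shared
    with the benchmark, so missing chapters are treated as unobserved rather
    than as zero-length stays.
    """
    shared = _shared(specialties, benchmark)
    d_all = sum(s.discharges for s in shared)
    num = sum(benchmark.ref_avlos[s.specialty] * s.discharges / d_all for s in shared)
    return num / benchmark.overall_avlos


def compute_pi(specialties, benchmark: Benchmark) -> float:
    """Performance Index of a structure's stay lengths against the benchmark.

    Benchmark discharge shares are renormalised over the shared specialty
    set, mirroring :func:`compute_cmi`.
    """
    shared = _shared(specialties, benchmark)
    ref_total = sum(benchmark.ref_discharges[s.specialty] for s in shared)
    num = sum(
        s.avlos * benchmark.ref_discharges[s.specialty] / ref_total for s in shared
    )
    return num / benchmark.overall_avlos


def classify_quadrant(cmi: float, pi: float) -> Quadrant:
    """Map a (CMI, PI) pair to its quadrant.

    Thresholds are strict: CMI > 1 counts as high complexity and PI < 1 as
    on-target performance, so equality with 1 classifies as outside target.
    """
    if not (math.isfinite(cmi) and math.isfinite(pi)) or cmi <= 0 or pi <= 0:
        raise DomainError(f"invalid (cmi, pi) = ({cmi}, {pi})")
    if pi < 1.0:
        return Quadrant.GREEN if cmi > 1.0 else Quadrant.YELLOW
    return Quadrant.ORANGE if cmi > 1.0 else Quadrant.RED


def pi_cmi_ratio(cmi: float, pi: float) -> float:
    """PI / CMI, the colouring scale of the quadrant map (higher = better)."""
    if cmi == 0:
        raise DomainError("pi/cmi ratio undefined for cmi == 0")
    return pi / cmi


def casemix_result(specialties, benchmark: Benchmark) -> CaseMixResult:
    """Convenience wrapper: CMI, PI, quadrant and coverage in one call."""
    cmi = compute_cmi(specialties, benchmark)
    pi = compute_pi(specialties, benchmark)
    return CaseMixResult(
        cmi=cmi,
        pi=pi,
        quadrant=classify_quadrant(cmi, pi),
        coverage=coverage_fraction(specialties, benchmark),
    )
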