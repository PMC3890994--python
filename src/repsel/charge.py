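"""CDR3 net-charge profiles and between-library charge shifts.

The net charge of a CDR3 is the integer sum of per-residue charges: Lys and
Arg +1, Asp and Glu −1, everything else 0 under the default physiological-pH
convention (His neutral; a His=+1 scheme is provided).  Ambiguity codes (X)
contribute 0.  A library's charge profile weights every unique CDR3 by its
read count, so the profile totals equal the filtered read totals exactly, and
between-library comparisons report per-bin and aggregate fold changes of the
normalized frequencies (neutral bin {0}; strong-negative ≤ −4;
strong-positive ≥ +4 by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .enrichment import CdrCountTable

__all__ = [
    "ChargeScheme",
    "ChargeProfile",
    "ChargeComparison",
    "AggregateBin",
    "DEFAULT_SCHEME",
    "HIS_POSITIVE_SCHEME",
    "DEFAULT_AGGREGATES",
    "net_charge",
    "charge_distribution",
    "compare_profiles",
]

_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class ChargeScheme:
    """Integer per-residue charge map over the 20 standard residues plus X."""

    name: str
    charges: Mapping[str, int]

    def __post_init__(self) -> None:
        missing = set(_AMINO_ACIDS + "X") - set(self.charges)
        if missing:
            raise ValueError(f"scheme {self.name!r} lacks residues {sorted(missing)}")

    def charge_of(self, residue: str) -> int:
        return self.charges[residue]


def _scheme(name: str, **overrides: int) -> ChargeScheme:
    charges = {aa: 0 for aa in _AMINO_ACIDS + "X"}
    charges.update(overrides)
    return ChargeScheme(name, charges)


#: physiological-pH convention: His neutral
DEFAULT_SCHEME = _scheme("default", K=1, R=1, D=-1, E=-1)
#: alternative counting protonated His as +1
HIS_POSITIVE_SCHEME = _scheme("histidine_positive", K=1, R=1, H=1, D=-1, E=-1)

SCHEMES = {s.name: s for s in (DEFAULT_SCHEME, HIS_POSITIVE_SCHEME)}


def net_charge(cdr3_aa: str, scheme: ChargeScheme = DEFAULT_SCHEME) -> int:
    """Integer net charge of a CDR3 amino-acid sequence (empty → 0)."""
    total = 0
    for i, residue in enumerate(cdr3_aa):
        try:
            total += scheme.charge_of(residue)
        except KeyError:
            raise ValueError(
                f"illegal residue {residue!r} at position {i} of {cdr3_aa!r}"
            ) from None
    return total


@dataclass
class ChargeProfile:
    """Read-weighted histogram of CDR3 net charge for one library/chain."""

    library_id: str
    chain: str
    bins: dict[int, int] = field(default_factory=dict)
    scheme_name: str = DEFAULT_SCHEME.name

    @property
    def total(self) -> int:
        return sum(self.bins.values())

    def normalized(self) -> dict[int, float]:
        total = self.total
        if total == 0:
            return {}
        return {c: w / total for c, w in sorted(self.bins.items())}

    def to_frame(self) -> pd.DataFrame:
        norm = self.normalized()
        items = sorted(self.bins.items())
        return pd.DataFrame({
            "library_id": self.library_id, "chain": self.chain,
            "charge": [c for c, _ in items],
            "weight": [w for _, w in items],
            "frequency": [norm[c] for c, _ in items]})


def charge_distribution(counts: CdrCountTable,
                        scheme: ChargeScheme = DEFAULT_SCHEME,
                        per_unique: bool = False) -> ChargeProfile:
    """Bin a count table by CDR3 net charge.

    Each CDR3 contributes its read count to its charge bin (``per_unique``
    weights every unique CDR3 as 1 instead); integer accounting is exact, so
    the profile total equals the table total (or the number of unique CDR3s).
    """
    if not counts.counts:
        raise ValueError(f"{counts.library_id}: empty count table")
    bins: dict[int, int] = {}
    for cdr3, count in counts.counts.items():
        c = net_charge(cdr3, scheme)
        bins[c] = bins.get(c, 0) + (1 if per_unique else count)
    return ChargeProfile(counts.library_id, counts.chain, bins, scheme.name)


@dataclass(frozen=True)
class AggregateBin:
    """A closed integer charge range [lo, hi] (None = unbounded)."""

    name: str
    lo: Optional[int] = None
    hi: Optional[int] = None

    def contains(self, charge: int) -> bool:
        return ((self.lo is None or charge >= self.lo)
                and (self.hi is None or charge <= self.hi))


DEFAULT_AGGREGATES: tuple[AggregateBin, ...] = (
    AggregateBin("neutral", 0, 0),
    AggregateBin("strong_negative", None, -4),
    AggregateBin("strong_positive", 4, None),
)


@dataclass
class ChargeComparison:
    """Per-bin and aggregate fold changes of normalized charge frequencies."""

    reference_id: str
    enriched_id: str
    chain: str
    per_bin: pd.DataFrame
    aggregates: pd.DataFrame

    def aggregate_fold(self, name: str) -> float:
        row = self.aggregates.loc[self.aggregates["aggregate"] == name]
        if row.empty:
            raise KeyError(f"no aggregate named {name!r}")
        return float(row["fold_change"].iloc[0])


def compare_profiles(reference: ChargeProfile, enriched: ChargeProfile,
                     aggregates: Sequence[AggregateBin] = DEFAULT_AGGREGATES,
                     ) -> ChargeComparison:
    """Fold changes of normalized charge frequencies, enriched over reference.

    An empty reference bin with a non-empty enriched bin reports an infinite
    fold change (both frequencies stay attached); an empty-empty bin reports
    NaN.  Profiles must be same-chain and non-empty.
    """
    if reference.chain != enriched.chain:
        raise ValueError(f"chain mismatch: {reference.chain!r} vs {enriched.chain!r}")
    if reference.total == 0 or enriched.total == 0:
        raise ValueError("both profiles must have positive total weight")
    ref = reference.normalized()
    enr = enriched.normalized()
    charges = sorted(set(ref) | set(enr))

    def fold(rf: float, ef: float) -> float:
        if rf > 0:
            return ef / rf
        return math.inf if ef > 0 else math.nan

    per_bin = pd.DataFrame({
        "charge": charges,
        "reference_freq": [ref.get(c, 0.0) for c in charges],
        "enriched_freq": [enr.get(c, 0.0) for c in charges]})
    per_bin["fold_change"] = [fold(r, e) for r, e in
                              zip(per_bin["reference_freq"], per_bin["enriched_freq"])]

    rows = []
    for agg in aggregates:
        rf = sum(f for c, f in ref.items() if agg.contains(c))
        ef = sum(f for c, f in enr.items() if agg.contains(c))
        rows.append({"aggregate": agg.name, "reference_freq": rf,
                     "enriched_freq": ef, "fold_change": fold(rf, ef)})
    return ChargeComparison(reference.library_id, enriched.library_id,
                            reference.chain, per_bin, pd.DataFrame(rows))
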