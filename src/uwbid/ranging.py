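"""Double-sided two-way ranging (DS-TWR) distance estimation.

A DS-TWR exchange between a mobile tag and a fixed anchor consists of
three messages (poll, response, final) producing six timestamps, three on
each device's local clock:

    tag clock:    t0 (poll tx),   ti (response rx),  t4 (final tx)
    anchor clock: ti1 (poll rx),  ti2 (response tx), ti3 (final rx)

The symmetric DS-TWR estimator

    tof = [ (ti - t0)(ti3 - ti2) - (ti2 - ti1)(t4 - ti) ]
          / [ (ti - t0) + (ti3 - ti2) + (ti2 - ti1) + (t4 - ti) ]

cancels both devices' reply delays exactly under ideal clocks and
suppresses first-order clock offset, which is why neither device needs to
be synchronised.  Distances follow as ``tof * c``.

All timestamps are continuous seconds; no radio tick arithmetic is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "SPEED_OF_LIGHT",
    "AnchorRecord",
    "RangingExchange",
    "RangingResult",
    "DegenerateExchangeError",
    "compute_distance",
    "compute_all_distances",
    "read_ranging_log",
    "write_ranging_log",
]

#: Speed of light in vacuum, m/s.
SPEED_OF_LIGHT = 299_792_458.0


class DegenerateExchangeError(ValueError):
    """Raised when an exchange's interval sum is non-positive."""


@dataclass(frozen=True)
class AnchorRecord:
    """Per-anchor half of one DS-TWR exchange.

    ``ti`` is on the tag's clock; ``ti1 < ti2 < ti3`` are on the anchor's
    clock (poll received, response transmitted, final received).
    """

    anchor_id: str
    ti: float
    ti1: float
    ti2: float
    ti3: float

    def __post_init__(self) -> None:
        for name in ("ti", "ti1", "ti2", "ti3"):
            v = getattr(self, name)
            if not (v == v and abs(v) != float("inf")) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {v!r}")
        if not (self.ti1 < self.ti2 < self.ti3):
            raise ValueError(
                f"anchor-clock ordering violated for {self.anchor_id}: "
                f"ti1={self.ti1} ti2={self.ti2} ti3={self.ti3}"
            )


@dataclass(frozen=True)
class RangingExchange:
    """One complete DS-TWR round between a tag and one or more anchors."""

    tag_id: str
    t0: float
    t4: float
    anchors: tuple[AnchorRecord, ...]
    exchange_id: str = ""

    def __post_init__(self) -> None:
        if not self.anchors:
            raise ValueError("exchange needs at least one anchor record")
        if not self.t0 < self.t4:
            raise ValueError(f"tag ordering violated: t0={self.t0} >= t4={self.t4}")
        for rec in self.anchors:
            if not (self.t0 < rec.ti < self.t4):
                raise ValueError(
                    f"tag-clock ordering violated for anchor {rec.anchor_id}: "
                    f"t0={self.t0} ti={rec.ti} t4={self.t4}"
                )

    def record(self, anchor_id: str) -> AnchorRecord:
        for rec in self.anchors:
            if rec.anchor_id == anchor_id:
                return rec
        raise KeyError(f"no record for anchor {anchor_id!r} in exchange {self.exchange_id!r}")

    @property
    def anchor_ids(self) -> tuple[str, ...]:
        return tuple(rec.anchor_id for rec in self.anchors)


@dataclass
class RangingResult:
    """Distances from one exchange: anchor id -> metres.

    ``clamped`` lists anchors whose raw estimate came out negative (possible
    under heavy timestamp noise) and was clamped to zero.
    """

    tag_id: str
    distances: dict[str, float]
    timestamp: float
    clamped: list[str] = field(default_factory=list)


def compute_distance(exchange: RangingExchange, anchor_id: str) -> float:
    """Tag-anchor distance in metres from one exchange's timestamps.

    Negative estimates are clamped to 0 (recorded by
    :func:`compute_all_distances`); a non-positive interval sum raises
    :class:`DegenerateExchangeError`.
    """
    rec = exchange.record(anchor_id)
    round1 = rec.ti - exchange.t0
    round2 = rec.ti3 - rec.ti2
    reply1 = rec.ti2 - rec.ti1
    reply2 = exchange.t4 - rec.ti
    denom = round1 + round2 + reply1 + reply2
    if denom <= 0:
        raise DegenerateExchangeError(
            f"non-positive interval sum {denom} for anchor {anchor_id} "
            f"in exchange {exchange.exchange_id!r}"
        )
    tof = (round1 * round2 - reply1 * reply2) / denom
    return max(tof * SPEED_OF_LIGHT, 0.0)


def compute_all_distances(exchange: RangingExchange) -> RangingResult:
    """Apply :func:`compute_distance` to every anchor record of an exchange."""
    distances: dict[str, float] = {}
    clamped: list[str] = []
    for rec in exchange.anchors:
        round1 = rec.ti - exchange.t0
        round2 = rec.ti3 - rec.ti2
        reply1 = rec.ti2 - rec.ti1
        reply2 = exchange.t4 - rec.ti
        denom = round1 + round2 + reply1 + reply2
        if denom <= 0:
            raise DegenerateExchangeError(
                f"non-positive interval sum {denom} for anchor {rec.anchor_id} "
                f"in exchange {exchange.exchange_id!r}"
            )
        d = (round1 * round2 - reply1 * reply2) / denom * SPEED_OF_LIGHT
        if d < 0:
            clamped.append(rec.anchor_id)
            d = 0.0
        distances[rec.anchor_id] = d
    return RangingResult(
        tag_id=exchange.tag_id,
        distances=distances,
        timestamp=exchange.t0,
        clamped=clamped,
    )


# ---------------------------------------------------------------------------
# Ranging-log CSV: one row per (exchange, anchor)

_LOG_COLUMNS = ["exchange_id", "tag_id", "anchor_id", "t0", "ti", "t4", "ti1", "ti2", "ti3"]


def write_ranging_log(exchanges: Iterable[RangingExchange], path) -> None:
    rows = []
    for ex in exchanges:
        for rec in ex.anchors:
            rows.append(
                {
                    "exchange_id": ex.exchange_id,
                    "tag_id": ex.tag_id,
                    "anchor_id": rec.anchor_id,
                    "t0": ex.t0,
                    "ti": rec.ti,
                    "t4": ex.t4,
                    "ti1": rec.ti1,
                    "ti2": rec.ti2,
                    "ti3": rec.ti3,
                }
            )
    # full float precision: nanosecond-scale intervals survive the round trip
    pd.DataFrame(rows, columns=_LOG_COLUMNS).to_csv(path, index=False, float_format="%.17g")


def read_ranging_log(path, *, skip_bad_rows: bool = True) -> tuple[list[RangingExchange], int]:
    """Read a ranging-log CSV; returns (exchanges, number of rows skipped).

    Rows that fail the timestamp-ordering invariants are dropped (and
    counted) when ``skip_bad_rows`` is true, raised otherwise.
    """
    df = pd.read_csv(path)
    missing = set(_LOG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"ranging log missing columns: {sorted(missing)}")
    exchanges: list[RangingExchange] = []
    skipped = 0
    for (exch_id, tag_id), grp in df.groupby(["exchange_id", "tag_id"], sort=False):
        records = []
        t0 = t4 = None
        for row in grp.itertuples(index=False):
            try:
                rec = AnchorRecord(
                    anchor_id=str(row.anchor_id),
                    ti=float(row.ti),
                    ti1=float(row.ti1),
                    ti2=float(row.ti2),
                    ti3=float(row.ti3),
                )
                if t0 is None:
                    t0, t4 = float(row.t0), float(row.t4)
                if not (float(row.t0) < rec.ti < float(row.t4)):
                    raise ValueError("tag-clock ordering violated")
            except (ValueError, TypeError) as err:
                if not skip_bad_rows:
                    raise ValueError(f"bad row in exchange {exch_id!r}: {err}") from err
                skipped += 1
                continue
            records.append(rec)
        if records and t0 is not None:
            exchanges.append(
                RangingExchange(
                    tag_id=str(tag_id),
                    t0=t0,
                    t4=t4,
                    anchors=tuple(records),
                    exchange_id=str(exch_id),
                )
            )
    return exchanges, skipped
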