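"""Read, reconcile, zero-fill, filter and write bilateral trade matrices.

Flows are stored long-format (one row per reported sender→receiver→year
quantity) and assembled into a dense ``TradeTensor`` with explicit zeros for
unreported dyad-years.  Exporter-reported values take precedence over
importer-reported ones when both exist for the same dyad-year.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd

from tradeflow.errors import FormatError, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from tradeflow.design import CountryPanel

logger = logging.getLogger(__name__)

EXPORTER_REPORTED = "exporter_reported"
IMPORTER_REPORTED = "importer_reported"

#: canonical write-side header
_CANONICAL_COLUMNS = ("sender", "receiver", "year", "quantity_tonnes")
#: accepted aliases on the read side
_COLUMN_ALIASES = {
    "reporter": "sender",
    "partner": "receiver",
    "quantity": "quantity_tonnes",
}


@dataclass(frozen=True)
class FlowRecord:
    """One reported bilateral flow.

    ``sender``/``receiver`` are country codes oriented in the direction of
    physical flow; ``source`` records whose report the value came from.
    """

    sender: str
    receiver: str
    year: int
    quantity: float
    source: str = EXPORTER_REPORTED

    def __post_init__(self) -> None:
        if self.sender == self.receiver:
            raise ValidationError(
                f"flow with sender == receiver ({self.sender!r}, year {self.year})"
            )
        if not np.isfinite(self.quantity) or self.quantity < 0:
            raise ValidationError(
                f"quantity must be finite and >= 0, got {self.quantity!r} "
                f"for {self.sender}->{self.receiver} in {self.year}"
            )
        if self.source not in (EXPORTER_REPORTED, IMPORTER_REPORTED):
            raise ValidationError(f"unknown source {self.source!r}")


@dataclass
class TradeTensor:
    """Dense directed flow quantities indexed by (sender, receiver, year).

    ``values[i, j, t]`` is the flow from ``countries[i]`` to ``countries[j]``
    in ``years[t]`` (tonnes).  The diagonal is identically zero.
    """

    countries: list[str]
    years: list[int]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        n, t = len(self.countries), len(self.years)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (n, n, t):
            raise ValidationError(
                f"values shape {self.values.shape} != ({n}, {n}, {t})"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("tensor contains non-finite entries")
        if np.any(self.values < 0):
            raise ValidationError("tensor contains negative quantities")
        diag = self.values[np.arange(n), np.arange(n), :]
        if np.any(diag != 0):
            raise ValidationError("tensor diagonal must be identically zero")

    @property
    def n_countries(self) -> int:
        return len(self.countries)

    @property
    def n_years(self) -> int:
        return len(self.years)

    def n_dyads(self) -> int:
        """Number of ordered country pairs (excluding self-pairs) per year."""
        n = self.n_countries
        return n * (n - 1)

    def year_matrix(self, year: int) -> np.ndarray:
        """The (N, N) flow matrix for one year."""
        return self.values[:, :, self.years.index(year)]

    def country_index(self, code: str) -> int:
        return self.countries.index(code)


def _normalise_columns(df: pd.DataFrame) -> pd.DataFrame:
    renamed = df.rename(columns={c: _COLUMN_ALIASES.get(c, c) for c in df.columns})
    missing = [c for c in _CANONICAL_COLUMNS if c not in renamed.columns]
    if missing:
        raise FormatError(
            "trade matrix is missing required column(s): " + ", ".join(missing)
        )
    return renamed


def read_trade_matrix(path, source: str = EXPORTER_REPORTED) -> list[FlowRecord]:
    """Parse a long-format bilateral trade CSV into flow records.

    The header may use either (sender, receiver, year, quantity_tonnes) or
    the reporter-oriented aliases (reporter, partner, year, quantity).
    Malformed numerics, negative quantities and self-flows are rejected with
    the offending row index.
    """
    df = pd.read_csv(path, dtype={0: str}, float_precision="round_trip")
    df = _normalise_columns(df)
    records: list[FlowRecord] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        try:
            year = int(getattr(row, "year"))
            quantity = float(getattr(row, "quantity_tonnes"))
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"malformed numeric field at row {idx}: {exc}")
        if not np.isfinite(quantity) or quantity < 0:
            raise ValidationError(
                f"negative or non-finite quantity {quantity!r} at row {idx}"
            )
        sender = str(getattr(row, "sender"))
        receiver = str(getattr(row, "receiver"))
        if sender == receiver:
            raise ValidationError(f"sender == receiver ({sender!r}) at row {idx}")
        records.append(FlowRecord(sender, receiver, year, quantity, source))
    return records


def merge_reported_flows(
    exports: Iterable[FlowRecord], imports: Iterable[FlowRecord]
) -> list[FlowRecord]:
    """Fill gaps in exporter-reported flows with importer-reported values.

    Importer-side records are given from the receiver's perspective
    (sender field = importing country) and are re-oriented during the merge.
    For each (sender, receiver, year) the exporter-reported value wins when
    both sides report; dyad-years reported by neither are absent.
    """
    merged: dict[tuple[str, str, int], FlowRecord] = {}
    for rec in imports:
        # flip orientation: importer reported "I received q from partner"
        flipped = FlowRecord(
            sender=rec.receiver,
            receiver=rec.sender,
            year=rec.year,
            quantity=rec.quantity,
            source=IMPORTER_REPORTED,
        )
        merged[(flipped.sender, flipped.receiver, flipped.year)] = flipped
    for rec in exports:
        if rec.source != EXPORTER_REPORTED:
            rec = FlowRecord(
                rec.sender, rec.receiver, rec.year, rec.quantity, EXPORTER_REPORTED
            )
        merged[(rec.sender, rec.receiver, rec.year)] = rec
    return [merged[k] for k in sorted(merged)]


def build_trade_tensor(
    flows: Iterable[FlowRecord],
    countries: Sequence[str],
    years: Sequence[int],
) -> TradeTensor:
    """Assemble a dense tensor, zero-filling unreported dyad-years.

    Flows naming countries outside ``countries`` are dropped (count logged).
    Duplicate (sender, receiver, year) entries with conflicting quantities
    raise: after merging there must be at most one value per cell.
    """
    if not len(countries) or not len(years):
        raise ValidationError("countries and years must be non-empty")
    countries = list(countries)
    years = [int(y) for y in years]
    cindex = {c: i for i, c in enumerate(countries)}
    yindex = {y: t for t, y in enumerate(years)}
    values = np.zeros((len(countries), len(countries), len(years)))
    seen: dict[tuple[int, int, int], float] = {}
    dropped = 0
    for rec in flows:
        if rec.sender not in cindex or rec.receiver not in cindex:
            dropped += 1
            continue
        if rec.year not in yindex:
            dropped += 1
            continue
        key = (cindex[rec.sender], cindex[rec.receiver], yindex[rec.year])
        if key in seen and seen[key] != rec.quantity:
            raise ValidationError(
                f"conflicting duplicate flow {rec.sender}->{rec.receiver} "
                f"in {rec.year}: {seen[key]} vs {rec.quantity}"
            )
        seen[key] = rec.quantity
        values[key] = rec.quantity
    if dropped:
        logger.info("dropped %d flow(s) outside the country/year lists", dropped)
    return TradeTensor(countries, years, values)


@dataclass
class FilterReport:
    """Which countries were removed and under which exclusion rule."""

    removed_missing_covariates: list[str]
    removed_zero_trade: list[str]

    @property
    def removed(self) -> list[str]:
        return sorted(set(self.removed_missing_covariates) | set(self.removed_zero_trade))


def filter_countries(
    tensor: TradeTensor, panel: "CountryPanel"
) -> tuple[TradeTensor, "CountryPanel", FilterReport]:
    """Apply the two country-exclusion rules until a fixed point.

    Rule 1 removes countries with any missing covariate value in any year.
    Rule 2 removes countries whose total trade (exports + imports summed
    over partners) is zero in at least one year.  Removals under rule 2 can
    zero out other countries' totals, so rule 2 is re-applied iteratively
    until stable.
    """
    from tradeflow.design import CountryPanel  # local import to avoid cycle

    if set(panel.years) != set(tensor.years):
        raise ValidationError("panel and tensor must share the same year range")

    covariates = ["gdp_pc", "population", "pasture_km2", "des_pct"]
    wide = panel.data.set_index(["country", "year"])[covariates]
    missing_by_country = wide.isna().groupby(level="country").any().any(axis=1)
    rule1 = sorted(c for c in tensor.countries if missing_by_country.get(c, True))

    keep = [c for c in tensor.countries if c not in set(rule1)]
    rule2: list[str] = []
    while True:
        if not keep:
            raise ValidationError("all countries removed by exclusion rules")
        idx = np.array([tensor.countries.index(c) for c in keep])
        sub = tensor.values[np.ix_(idx, idx)]  # (k, k, T)
        totals = sub.sum(axis=1) + sub.sum(axis=0)  # exports + imports, (k, T)
        bad = np.any(totals == 0, axis=1)
        if not bad.any():
            break
        rule2.extend(keep[i] for i in np.flatnonzero(bad))
        keep = [c for i, c in enumerate(keep) if not bad[i]]

    idx = np.array([tensor.countries.index(c) for c in keep])
    new_tensor = TradeTensor(keep, list(tensor.years), tensor.values[np.ix_(idx, idx)])
    keep_set = set(keep)
    new_panel = CountryPanel(
        data=panel.data[panel.data["country"].isin(keep_set)].reset_index(drop=True),
        coords=panel.coords[panel.coords["country"].isin(keep_set)].reset_index(drop=True),
    )
    report = FilterReport(rule1, sorted(rule2))
    return new_tensor, new_panel, report


def write_trade_matrix(tensor: TradeTensor, path, omit_zeros: bool = False) -> None:
    """Write a tensor back to long-format CSV (canonical header).

    ``read_trade_matrix(write_trade_matrix(t))`` is the identity on nonzero
    flows; with ``omit_zeros`` the explicit zero cells are not written.
    """
    n = tensor.n_countries
    senders, receivers, years_, quantities = [], [], [], []
    for i, s in enumerate(tensor.countries):
        for j, r in enumerate(tensor.countries):
            if i == j:
                continue
            for t, y in enumerate(tensor.years):
                q = tensor.values[i, j, t]
                if omit_zeros and q == 0:
                    continue
                senders.append(s)
                receivers.append(r)
                years_.append(y)
                quantities.append(q)
    df = pd.DataFrame(
        {
            "sender": senders,
            "receiver": receivers,
            "year": years_,
            "quantity_tonnes": quantities,
        }
    )
    # %.17g round-trips IEEE doubles exactly
    df.to_csv(path, index=False, float_format="%.17g")
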