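"""Sets of significant integer lags and their run notation.

Significant lag sets are reported in the compact run-of-consecutive-days
notation used throughout the results tables, e.g. ``"1-3 and 5-6"`` for
{1,2,3,5,6}, a single run ``"1-8"`` for {1..8}, and ``"n.s."`` for the empty
set (no significant lag identified).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator


def _runs(lags: tuple[int, ...]) -> list[tuple[int, int]]:
    runs: list[tuple[int, int]] = []
    for lag in lags:
        if runs and lag == runs[-1][1] + 1:
            runs[-1] = (runs[-1][0], lag)
        else:
            runs.append((lag, lag))
    return runs


def format_lag_runs(lags: Iterable[int]) -> str:
    """Render an integer lag set in run notation (``"n.s."`` if empty)."""
    ordered = tuple(sorted(set(int(l) for l in lags)))
    if not ordered:
        return "n.s."
    parts = [f"{a}" if a == b else f"{a}-{b}" for a, b in _runs(ordered)]
    return " and ".join(parts)


def parse_lag_runs(text: str) -> tuple[int, ...]:
    """Inverse of :func:`format_lag_runs`."""
    text = text.strip()
    if not text or text == "n.s.":
        return ()
    lags: set[int] = set()
    for part in text.replace(",", " and ").split(" and "):
        part = part.strip()
        if not part:
            continue
        if "-" in part:
            a, b = part.split("-")
            lags.update(range(int(a), int(b) + 1))
        else:
            lags.add(int(part))
    return tuple(sorted(lags))


@dataclass(frozen=True)
class LagSet:
    """An ordered set of integer lags flagged significant at level ``alpha``."""

    lags: tuple[int, ...] = ()
    alpha: float = 0.05

    def __post_init__(self) -> None:
        object.__setattr__(self, "lags", tuple(sorted(set(int(l) for l in self.lags))))
        if self.lags and self.lags[0] < 1:
            raise ValueError("lags must be positive integers")

    def __iter__(self) -> Iterator[int]:
        return iter(self.lags)

    def __len__(self) -> int:
        return len(self.lags)

    def __bool__(self) -> bool:
        return bool(self.lags)

    def __contains__(self, lag: object) -> bool:
        return lag in self.lags

    def __str__(self) -> str:
        return format_lag_runs(self.lags)
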