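"""Aggregation of multi-target screens: yield distributions, deletion
frequencies, and knockout-count tables."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .engine import DeletionTrace, RunConfig, run_aerith
from .fba_core import FBAConfig, apply_exchange_policy
from .model import MetabolicModel


@dataclass(frozen=True)
class TargetRecord:
    """Outcome of one target's deletion search."""

    target_exchange: str
    theoretical_max: float
    final_target_flux: float
    yield_fraction: float
    deletions: tuple[str, ...]
    terminal_status: str
    productive: bool


@dataclass
class ScreenResult:
    records: list[TargetRecord]

    def __post_init__(self) -> None:
        targets = [r.target_exchange for r in self.records]
        if len(set(targets)) != len(targets):
            raise ValueError("duplicate targets in screen result")

    @classmethod
    def from_traces(cls, traces: Iterable[DeletionTrace], y_obj: float = 1e-3) -> "ScreenResult":
        records = []
        for tr in traces:
            flux = tr.final_target_flux if tr.steps else 0.0
            yld = tr.final_yield_fraction if tr.steps else 0.0
            records.append(
                TargetRecord(
                    target_exchange=tr.target_exchange,
                    theoretical_max=tr.theoretical_max,
                    final_target_flux=0.0 if np.isnan(flux) else flux,
                    yield_fraction=0.0 if np.isnan(yld) else yld,
                    deletions=tuple(tr.deletions),
                    terminal_status=tr.terminal_status,
                    productive=bool(not np.isnan(flux) and flux >= y_obj),
                )
            )
        return cls(records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records])


def screen_targets(
    model: MetabolicModel,
    targets: Sequence[str],
    fba_config: FBAConfig,
    run_config: RunConfig = RunConfig(),
) -> tuple[ScreenResult, list[DeletionTrace]]:
    """Run the deletion search for every target, applying the exchange-bound
    policy per target, and collect the per-target outcomes."""
    traces = []
    for target in targets:
        bounded = apply_exchange_policy(model, target, fba_config)
        traces.append(run_aerith(bounded, target, fba_config, run_config))
    return ScreenResult.from_traces(traces, run_config.y_obj), traces


def yield_distribution(results: ScreenResult, bin_width: float = 0.1) -> pd.DataFrame:
    """Histogram of achieved yields in 10%-wide bins plus the cumulative
    count read from the high-yield end.

    Only targets with a productive design are binned; counts therefore sum
    to the number of productive targets, and the cumulative column gives
    "number of targets achieving at least this bin's yield".
    """
    if not results.records:
        raise ValueError("empty screen result")
    productive = [r.yield_fraction for r in results.records if r.productive]
    edges = np.round(np.arange(0.0, 1.0 + bin_width / 2, bin_width), 10)
    counts = np.zeros(len(edges) - 1, dtype=int)
    for y in productive:
        # right-inclusive bins: a yield of exactly 10% belongs to the 0-10% bin
        i = int(np.ceil(round(y / bin_width, 9))) - 1
        counts[min(max(i, 0), len(counts) - 1)] += 1
    frame = pd.DataFrame(
        {
            "bin_low": edges[:-1],
            "bin_high": edges[1:],
            "count": counts,
        }
    )
    frame["cumulative_from_high"] = counts[::-1].cumsum()[::-1]
    return frame


def deletion_frequency(results: ScreenResult, top_n: int | None = None) -> pd.DataFrame:
    """Reactions ranked by how many targets' final deletion sets contain
    them; ties resolved lexicographically.  Computed from the stored
    records alone (no re-solving)."""
    if not results.records:
        raise ValueError("empty screen result")
    counter: Counter[str] = Counter()
    for rec in results.records:
        counter.update(set(rec.deletions))
    ranked = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    if top_n is not None:
        ranked = ranked[: max(top_n, 0)]
    return pd.DataFrame(ranked, columns=["reaction_id", "n_targets"])


def knockout_count_table(
    model: MetabolicModel,
    target_exchange: str,
    fba_config: FBAConfig,
    run_config: RunConfig = RunConfig(),
    rows: Sequence[int] = (),
    trace: DeletionTrace | None = None,
) -> pd.DataFrame:
    """Growth and target flux at the requested knockout counts.

    Reads the fluxes off a deletion trace (running the search if none is
    supplied); counts beyond the trace length are marked unavailable.
    """
    if trace is None:
        bounded = apply_exchange_policy(model, target_exchange, fba_config)
        trace = run_aerith(bounded, target_exchange, fba_config, run_config)
    by_k = {s.k: s for s in trace.steps}
    out = []
    for k in rows:
        step = by_k.get(k)
        if step is None:
            out.append({"knockouts": k, "biomass_flux": np.nan, "target_flux": np.nan,
                        "available": False})
        else:
            out.append(
                {
                    "knockouts": k,
                    "biomass_flux": step.biomass_flux,
                    "target_flux": step.target_flux,
                    "available": step.status == "optimal",
                }
            )
    return pd.DataFrame(out)
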