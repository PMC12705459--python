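"""Collapse regional transition-energy tensors to network/global scales and
apply the IQR outlier rule on cohort mean global TE."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from brainte.cohort import ParcellationScheme


@dataclass(frozen=True)
class AggregatedTE:
    """All aggregation levels derived from one subject's regional tensor.

    network_pairwise follows the canonical network order restricted to the
    parcellation's populated networks (``networks`` records it).
    """

    subject_id: str
    networks: tuple[str, ...]
    network_pairwise: np.ndarray  # (n_networks, k, k)
    global_pairwise: np.ndarray  # (k, k)
    mean_regional: np.ndarray  # (N,)
    mean_network: np.ndarray  # (n_networks,)
    mean_global: float


@dataclass(frozen=True)
class OutlierReport:
    lower_fence: float
    upper_fence: float
    excluded_subject_ids: tuple[str, ...]

    @property
    def n_excluded(self) -> int:
        return len(self.excluded_subject_ids)


def aggregate(
    tensor: np.ndarray, parcellation: ParcellationScheme, subject_id: str = ""
) -> AggregatedTE:
    """Sum regions into networks and globally; means average all k^2
    pairwise entries (persistence diagonal included)."""
    tensor = np.asarray(tensor, dtype=float)
    if tensor.ndim != 3 or tensor.shape[1] != tensor.shape[2]:
        raise ValueError("tensor must have shape (N, k, k)")
    if tensor.shape[0] != parcellation.n_regions:
        raise ValueError(
            f"tensor has {tensor.shape[0]} regions but parcellation has {parcellation.n_regions}"
        )
    nets = parcellation.present_networks
    network_pairwise = np.stack(
        [tensor[parcellation.regions_of(n)].sum(axis=0) for n in nets]
    )
    global_pairwise = tensor.sum(axis=0)
    return AggregatedTE(
        subject_id=subject_id,
        networks=nets,
        network_pairwise=network_pairwise,
        global_pairwise=global_pairwise,
        mean_regional=tensor.mean(axis=(1, 2)),
        mean_network=network_pairwise.mean(axis=(1, 2)),
        mean_global=float(global_pairwise.mean()),
    )


def aggregate_cohort(
    tensors: dict[str, np.ndarray], parcellation: ParcellationScheme
) -> tuple[list[AggregatedTE], pd.DataFrame]:
    """Aggregate every subject and return a wide per-subject table
    (mean_global, mean_<network>, mean_<region_name>)."""
    aggs = [aggregate(t, parcellation, subject_id=sid) for sid, t in tensors.items()]
    rows = []
    for a in aggs:
        row: dict[str, object] = {"subject_id": a.subject_id, "mean_global": a.mean_global}
        row.update({f"mean_{n}": v for n, v in zip(a.networks, a.mean_network)})
        row.update(
            {f"mean_{r}": v for r, v in zip(parcellation.region_names, a.mean_regional)}
        )
        rows.append(row)
    return aggs, pd.DataFrame(rows)


def exclude_outliers(
    mean_global: pd.Series | dict[str, float], factor: float = 1.5
) -> OutlierReport:
    """Flag subjects whose mean global TE lies outside
    [Q1 - factor*IQR, Q3 + factor*IQR].

    Quartiles use linear interpolation between order statistics (the
    numpy default), a pinned convention.
    """
    series = pd.Series(mean_global, dtype=float)
    if len(series) < 4:
        raise ValueError("need at least 4 subjects for quartile fences")
    q1, q3 = np.percentile(series.to_numpy(), [25.0, 75.0])
    iqr = q3 - q1
    lo = q1 - factor * iqr
    hi = q3 + factor * iqr
    mask = (series < lo) | (series > hi)
    return OutlierReport(
        lower_fence=float(lo),
        upper_fence=float(hi),
        excluded_subject_ids=tuple(str(s) for s in series.index[mask]),
    )
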