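"""Per-position misincorporation rates, normalized reactivities, and summaries.

The raw signal is the per-position misincorporation rate
``r_i = misincorporations_i / coverage_i``.  Rates from different nucleotides
are not directly comparable (baseline DMS reactivity differs by base), so
rates are rescaled to reactivity values within each nucleotide class: box-plot
outliers (above Q3 + 1.5 IQR) are discarded, the normalization factor is the
mean of the top 10% of the remaining rates, and each rate is divided by the
factor.  A reactivity near 1 then means "as reactive as the most accessible
positions of that base".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ReadSet

__all__ = [
    "ReactivityProfile",
    "misincorporation_rates",
    "normalize_reactivity",
    "bottom_quartile_gs",
    "register_mean_rates",
    "roc_auc",
]


@dataclass
class ReactivityProfile:
    """Per-position rates and (optionally) normalized reactivities.

    ``data`` columns: position (1-based), base, coverage, rate, reactivity,
    flag.  ``rate`` is NaN where coverage < min_cov ("low_coverage" flag);
    ``reactivity`` is NaN until :func:`normalize_reactivity` runs.
    """

    data: pd.DataFrame
    min_cov: int = 0
    norm_params: dict = field(default_factory=dict)

    @property
    def L(self) -> int:
        return len(self.data)

    def rates(self) -> np.ndarray:
        return self.data["rate"].to_numpy()

    def reactivities(self) -> np.ndarray:
        return self.data["reactivity"].to_numpy()

    def rate_at(self, position: int) -> float:
        return float(self.data.loc[self.data["position"] == position, "rate"].iloc[0])

    def base_positions(self, base: str) -> np.ndarray:
        d = self.data
        return d.loc[d["base"] == base, "position"].to_numpy()

    def write_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_rates(cls, reference, rates, coverage=None, min_cov: int = 0):
        """Build a profile directly from a rate vector (e.g. mixture-state mu)."""
        rates = np.asarray(rates, dtype=float)
        L = len(reference)
        if coverage is None:
            coverage = np.full(L, np.inf)
        data = pd.DataFrame(
            {
                "position": np.arange(1, L + 1),
                "base": list(reference.seq),
                "coverage": coverage,
                "rate": rates,
                "reactivity": np.nan,
                "flag": "",
            }
        )
        return cls(data, min_cov=min_cov)


def misincorporation_rates(rs: ReadSet, min_cov: int = 100) -> ReactivityProfile:
    """Per-position rate = column sum of bits / column coverage.

    Positions covered by fewer than ``min_cov`` reads get a NaN rate and a
    "low_coverage" flag.
    """
    bits = rs.bits_matrix_padded()
    cov = rs.coverage_matrix().sum(axis=0)
    hits = bits.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(cov > 0, hits / np.maximum(cov, 1), np.nan)
    low = cov < min_cov
    rate = np.where(low, np.nan, rate)
    data = pd.DataFrame(
        {
            "position": np.arange(1, rs.L + 1),
            "base": list(rs.reference.seq),
            "coverage": cov,
            "rate": rate,
            "reactivity": np.nan,
            "flag": np.where(low, "low_coverage", ""),
        }
    )
    return ReactivityProfile(data, min_cov=min_cov)


def _norm_factor(rates: np.ndarray, iqr_mult: float, top_frac: float) -> float:
    """Box-plot outlier removal, then mean of the top fraction of the rest."""
    rates = rates[np.isfinite(rates)]
    if len(rates) == 0:
        return 0.0
    q1, q3 = np.percentile(rates, [25, 75])
    kept = rates[rates <= q3 + iqr_mult * (q3 - q1)]
    if len(kept) == 0:
        return 0.0
    n_top = max(1, int(np.ceil(top_frac * len(kept))))
    top = np.sort(kept)[-n_top:]
    return float(top.mean())


def normalize_reactivity(
    profile: ReactivityProfile,
    per_base: bool = True,
    iqr_mult: float = 1.5,
    top_frac: float = 0.10,
) -> ReactivityProfile:
    """Rescale rates to reactivities within each nucleotide class.

    With ``per_base`` each of A/C/G/U is normalized separately (bases differ
    in baseline DMS reactivity); otherwise a single pooled factor is used.
    A class whose factor is 0 (all-zero rates) is left unnormalized and its
    positions flagged "unnormalized".
    """
    data = profile.data.copy()
    groups = data.groupby("base").groups if per_base else {"all": data.index}
    factors: dict[str, float] = {}
    for cls, idx in groups.items():
        rates = data.loc[idx, "rate"].to_numpy(dtype=float)
        factor = _norm_factor(rates, iqr_mult, top_frac)
        factors[str(cls)] = factor
        if factor > 0:
            data.loc[idx, "reactivity"] = data.loc[idx, "rate"] / factor
        else:
            data.loc[idx, "reactivity"] = np.nan
            flagged = data.loc[idx, "flag"].astype(str)
            data.loc[idx, "flag"] = np.where(
                flagged == "", "unnormalized", flagged + ";unnormalized"
            )
    return ReactivityProfile(
        data,
        min_cov=profile.min_cov,
        norm_params={
            "per_base": per_base,
            "iqr_mult": iqr_mult,
            "top_frac": top_frac,
            "factors": factors,
        },
    )


def bottom_quartile_gs(profile: ReactivityProfile) -> set[int]:
    """G positions whose rate is at or below the 25th percentile of G rates.

    Ties at the cutoff are included; the percentile uses linear
    interpolation.  Returns an empty set when the sequence has no G's.
    """
    d = profile.data
    g = d[(d["base"] == "G") & np.isfinite(d["rate"])]
    if len(g) == 0:
        return set()
    cutoff = np.percentile(g["rate"].to_numpy(), 25)
    return set(g.loc[g["rate"] <= cutoff, "position"].astype(int).tolist())


def register_mean_rates(profile: ReactivityProfile, registers) -> pd.DataFrame:
    """Mean member-G misincorporation rate per quadruplex register.

    The register with the lowest mean rate (its G's are the most protected)
    is the candidate most-abundant conformation; rows are returned in input
    order with an ``is_min`` marker.
    """
    rows = []
    for reg in registers:
        members = list(reg.members) if hasattr(reg, "members") else list(reg)
        name = getattr(reg, "name", None) or f"register_{len(rows) + 1}"
        rates = np.array([profile.rate_at(p) for p in members], dtype=float)
        rows.append({"register": name, "n_members": len(members), "mean_rate": rates.mean()})
    out = pd.DataFrame(rows)
    out["is_min"] = np.isclose(out["mean_rate"], out["mean_rate"].min())
    return out


def roc_auc(
    profile: ReactivityProfile, labels: dict[int, str], bases=("A", "C", "U")
) -> dict[str, float]:
    """Per-base AUC for discriminating unpaired from paired positions.

    ``labels`` maps 1-based position -> "paired"/"unpaired".  The AUC is the
    probability that a random unpaired position out-rates a random paired
    one, ties counted half:
    AUC = P(r_u > r_p) + 0.5 P(r_u = r_p) over all cross pairs.
    """
    d = profile.data
    out: dict[str, float] = {}
    for b in bases:
        sub = d[(d["base"] == b) & np.isfinite(d["rate"])]
        unp = sub[sub["position"].map(labels.get) == "unpaired"]["rate"].to_numpy()
        par = sub[sub["position"].map(labels.get) == "paired"]["rate"].to_numpy()
        if len(unp) == 0 or len(par) == 0:
            out[b] = np.nan
            continue
        diff = unp[:, None] - par[None, :]
        out[b] = float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / diff.size)
    return out
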