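"""Small exactly-specified quantifications: % input, relative BrdU, densitometry.

ChIP-qPCR enrichment is reported as percent of input chromatin:

    % input = 100 * 2 ** (ct_input_adj - ct_ip)

where ``ct_input_adj = ct_input - log2(1 / input_fraction)`` corrects for the
aliquot of chromatin used as the input sample (``input_fraction = 1`` means
the Cts are already dilution-adjusted).

Relative BrdU fluorescence normalizes the net S-phase BrdU signal (S mean
minus BrdU-negative G1/G2M mean) to the same quantity in the control
condition.  Densitometry ratios normalize a band to histone H3 in the same
sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "QpcrMeasurement",
    "BrduQuant",
    "DensitometryQuant",
    "percent_input",
    "ct_table_percent_input",
    "origin_flank_profile",
    "relative_brdu",
    "densitometry_ratio",
]


@dataclass(frozen=True)
class QpcrMeasurement:
    amplicon: str
    ct_ip: float
    ct_input: float
    input_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.ct_ip <= 0 or self.ct_input <= 0:
            raise ValueError("Ct values must be positive")
        if not 0 < self.input_fraction <= 1:
            raise ValueError("input_fraction must be in (0, 1]")


@dataclass(frozen=True)
class BrduQuant:
    s_mean: float
    neg_mean: float
    reference_net: float

    def __post_init__(self) -> None:
        if self.s_mean < 0 or self.neg_mean < 0:
            raise ValueError("intensities must be >= 0")
        if not self.reference_net > 0:
            raise ValueError("reference_net must be positive")


@dataclass(frozen=True)
class DensitometryQuant:
    band_density: float
    h3_density: float

    def __post_init__(self) -> None:
        if self.band_density <= 0 or self.h3_density <= 0:
            raise ValueError("densities must be positive")


def percent_input(m: QpcrMeasurement) -> float:
    """ChIP enrichment as percent of (dilution-adjusted) input."""
    ct_input_adj = m.ct_input - np.log2(1.0 / m.input_fraction)
    return float(100.0 * 2.0 ** (ct_input_adj - m.ct_ip))


def ct_table_percent_input(table: pd.DataFrame) -> pd.DataFrame:
    """Percent input per amplicon from a long-form Ct table.

    Expects columns ``amplicon``, ``role`` ('IP'/'input'), ``ct`` and
    optionally ``input_fraction`` (default 1).
    """
    rows = []
    for amplicon, grp in table.groupby("amplicon", sort=False):
        roles = dict(zip(grp["role"], grp["ct"]))
        if "IP" not in roles or "input" not in roles:
            raise ValueError(f"amplicon {amplicon!r} lacks an IP or input Ct")
        frac = float(grp["input_fraction"].iloc[0]) \
            if "input_fraction" in grp else 1.0
        m = QpcrMeasurement(amplicon=str(amplicon), ct_ip=float(roles["IP"]),
                            ct_input=float(roles["input"]), input_fraction=frac)
        rows.append({"amplicon": amplicon, "percent_input": percent_input(m)})
    return pd.DataFrame(rows, columns=["amplicon", "percent_input"])


def origin_flank_profile(measurements: pd.DataFrame) -> pd.DataFrame:
    """Origin-versus-flank enrichment per locus.

    ``measurements`` has one row per amplicon with columns ``locus``,
    ``position`` ('ori' or a flank label such as '-5kb'/'+5kb'), ``ct_ip``,
    ``ct_input`` and optionally ``input_fraction``.  Emits % input per
    amplicon plus one summary row per locus with the ori / mean-flank ratio;
    loci with missing flanks are flagged and the ratio uses the flanks
    available.
    """
    rows = []
    for _, r in measurements.iterrows():
        m = QpcrMeasurement(
            amplicon=f"{r['locus']}:{r['position']}",
            ct_ip=float(r["ct_ip"]), ct_input=float(r["ct_input"]),
            input_fraction=float(r.get("input_fraction", 1.0)),
        )
        rows.append({"locus": r["locus"], "position": r["position"],
                     "percent_input": percent_input(m)})
    out = pd.DataFrame(rows, columns=["locus", "position", "percent_input"])
    summaries = []
    for locus, grp in out.groupby("locus", sort=False):
        ori = grp.loc[grp["position"] == "ori", "percent_input"]
        if ori.empty:
            raise ValueError(f"locus {locus!r} has no 'ori' amplicon")
        flanks = grp.loc[grp["position"] != "ori", "percent_input"]
        flagged = len(flanks) < 2
        ratio = float(ori.iloc[0] / flanks.mean()) if len(flanks) else np.nan
        summaries.append({"locus": locus, "ori_percent_input": float(ori.iloc[0]),
                          "flank_mean_percent_input":
                              float(flanks.mean()) if len(flanks) else np.nan,
                          "ori_flank_ratio": ratio,
                          "incomplete_flanks": flagged})
    return out, pd.DataFrame(summaries)


def relative_brdu(q: BrduQuant) -> float:
    """Net S-phase BrdU signal relative to the control condition's net signal."""
    net = q.s_mean - q.neg_mean
    if net < 0:
        warnings.warn("negative net BrdU signal clipped to 0", stacklevel=2)
        return 0.0
    return float(net / q.reference_net)


def densitometry_ratio(d: DensitometryQuant) -> float:
    """Band density normalized to H3 in the same sample (arbitrary units)."""
    return float(d.band_density / d.h3_density)
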