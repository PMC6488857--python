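"""Cross-platform fold-change concordance (microarray vs qRT-PCR).

For a panel of probes measured on both platforms, each platform's fold
change (linear, >= 1, with Up/Down direction) is mapped to a SIGNED
natural-log fold change: +ln(fc) for Up, -ln(fc) for Down. Concordance is
the Pearson correlation of the signed values across probes, one point per
probe. The signed mapping keeps direction: an unsigned ln of >= 1 folds
would collapse up- and down-regulation together and could never show
near-perfect concordance on a mixed panel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .array_io import CONTROL, TREATED, GROUPS
from .coexpression import pearson_r
from .diffexpr import DOWN, UP, _folded_ratio, _pooled_t


@dataclass
class QpcrTable:
    """Long-format relative quantities: one row per (probe, sample).

    ``data`` has columns probe, sample, quantity (> 0, reference-gene
    normalized); ``groups`` maps sample id -> control/treated.
    """

    data: pd.DataFrame = field(repr=False)
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = {"probe", "sample", "quantity"} - set(self.data.columns)
        if missing:
            raise ValueError(f"qPCR table missing columns: {sorted(missing)}")
        if len(self.data) and (self.data["quantity"] <= 0).any():
            raise ValueError("relative quantities must be positive")
        bad = set(self.groups.values()) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")

    @property
    def probes(self) -> list[str]:
        return list(dict.fromkeys(self.data["probe"]))

    def quantities(self, probe: str, group: str) -> np.ndarray:
        mask = (self.data["probe"] == probe) & self.data["sample"].map(self.groups).eq(group)
        return self.data.loc[mask, "quantity"].to_numpy(dtype=float)

    def write_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_qpcr_table(path, groups: dict[str, str]) -> QpcrTable:
    df = pd.read_csv(path, sep="\t", dtype={"probe": str, "sample": str})
    return QpcrTable(data=df, groups=dict(groups))


def qpcr_fold_change(qpcr: QpcrTable, probe: str) -> tuple[float, str, float]:
    """(fold change >= 1, direction, p) for one probe from relative quantities.

    Fold change is the ratio of group-mean quantities; p is a two-sided
    pooled t-test on ln-quantities (same zero-variance policy as the array
    screen).
    """
    qc = qpcr.quantities(probe, CONTROL)
    qt = qpcr.quantities(probe, TREATED)
    if len(qc) < 2 or len(qt) < 2:
        raise ValueError(f"probe {probe!r}: need >= 2 samples per group")
    ratio = float(qt.mean() / qc.mean())
    fc, reg = _folded_ratio(np.array([ratio]))
    p = float(_pooled_t(np.log(qt)[None, :], np.log(qc)[None, :], "pooled")[0])
    return float(fc[0]), str(reg[0]), p


def signed_ln(fold_change: float, regulation: str) -> float:
    """+ln(fc) for Up, -ln(fc) for Down."""
    if regulation not in (UP, DOWN):
        raise ValueError(f"unknown regulation {regulation!r}")
    value = math.log(fold_change)
    return value if regulation == UP else -value


@dataclass
class ValidationResult:
    """Per-probe cross-platform comparison plus the overall concordance."""

    table: pd.DataFrame = field(repr=False)
    r: float = float("nan")
    p_value: float = float("nan")
    n: int = 0

    def write_tsv(self, table_path, summary_path=None) -> None:
        self.table.to_csv(table_path, sep="\t", index=False, float_format="%.10g")
        if summary_path is not None:
            with open(summary_path, "w") as fh:
                fh.write("r\tp_value\tn\n")
                fh.write(f"{self.r:.10g}\t{self.p_value:.10g}\t{self.n}\n")


def platform_concordance(array_results: pd.DataFrame, qpcr: QpcrTable) -> ValidationResult:
    """Correlate signed ln fold changes across platforms, one point per probe.

    ``array_results`` is a DE-table subset (fold_change, regulation, p_value)
    indexed by probe; every probe must also be present in the qPCR table.
    """
    probes = [p for p in array_results.index if p in set(qpcr.probes)]
    if len(probes) < 3:
        raise ValueError("need >= 3 shared probes for a concordance correlation")
    rows = []
    for probe in probes:
        a_fc = float(array_results.at[probe, "fold_change"])
        a_reg = str(array_results.at[probe, "regulation"])
        q_fc, q_reg, q_p = qpcr_fold_change(qpcr, probe)
        rows.append(
            (
                probe,
                a_fc,
                a_reg,
                q_fc,
                q_reg,
                signed_ln(a_fc, a_reg),
                signed_ln(q_fc, q_reg),
                q_p,
            )
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "probe",
            "array_fc",
            "array_regulation",
            "qpcr_fc",
            "qpcr_regulation",
            "signed_ln_array",
            "signed_ln_qpcr",
            "qpcr_p_value",
        ],
    )
    r, p = pearson_r(table["signed_ln_array"], table["signed_ln_qpcr"])
    return ValidationResult(table=table, r=r, p_value=p, n=len(table))
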