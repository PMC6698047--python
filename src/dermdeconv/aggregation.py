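"""Collapse fine-grained fractions into coarse groups and summarize cohorts.

Cell-type fractions live on the simplex; grouping is a linear pooling (sum
of member fractions), so row totals are conserved exactly and group means
commute with aggregation. Reporting in percentage points multiplies by 100
at output only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

OTHERS = "others"


@dataclass
class GroupingScheme:
    """Group label -> member cell types; members must not overlap."""

    groups: dict[str, list[str]]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for g, members in self.groups.items():
            if not members:
                raise ValueError(f"empty group {g!r}")
            for ct in members:
                if ct in seen:
                    raise ValueError(f"cell type {ct!r} in groups {seen[ct]!r} and {g!r}")
                seen[ct] = g

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GroupingScheme":
        df = pd.read_csv(path, sep="\t", dtype=str)
        df.columns = ["group", "cell_type"] + list(df.columns[2:])
        groups: dict[str, list[str]] = {}
        for g, ct in zip(df["group"], df["cell_type"]):
            groups.setdefault(g, []).append(ct)
        return cls(groups)

    def to_tsv(self, path: str | Path) -> None:
        rows = [(g, ct) for g, members in self.groups.items() for ct in members]
        pd.DataFrame(rows, columns=["group", "cell_type"]).to_csv(path, sep="\t", index=False)


def aggregate_fractions(fractions: pd.DataFrame, scheme: GroupingScheme) -> pd.DataFrame:
    """Sum member fractions per group; leftover cell types pool into "others".

    Row totals are preserved (mass conservation).
    """
    known = set(fractions.columns)
    unknown = [ct for members in scheme.groups.values() for ct in members if ct not in known]
    if unknown:
        raise ValueError(f"scheme references unknown cell types: {unknown}")
    out = {}
    covered: set[str] = set()
    for g, members in scheme.groups.items():
        out[g] = fractions[members].sum(axis=1)
        covered.update(members)
    rest = [ct for ct in fractions.columns if ct not in covered]
    if rest:
        out[OTHERS] = out.get(OTHERS, 0) + fractions[rest].sum(axis=1)
    return pd.DataFrame(out, index=fractions.index)


def phenotype_composition(
    fractions: pd.DataFrame, metadata: pd.DataFrame, stratify_by: str | list[str]
) -> pd.DataFrame:
    """Mean, SD, SE and n per (stratum, cell type), long format.

    Single-sample strata report SD/SE of 0 with ``se_undefined`` flagged.
    Empty strata (levels present in metadata but matching no fraction row)
    are omitted with a warning.
    """
    keys = [stratify_by] if isinstance(stratify_by, str) else list(stratify_by)
    missing = set(fractions.index) - set(metadata.index)
    if missing:
        raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")
    md = metadata.loc[fractions.index, keys]
    rows = []
    for stratum, idx in sorted(md.groupby(keys, sort=True).groups.items(), key=str):
        block = fractions.loc[idx]
        n = len(block)
        if n == 0:
            logger.warning("empty stratum %r omitted", stratum)
            continue
        label = stratum if isinstance(stratum, str) else "/".join(map(str, stratum))
        for ct in fractions.columns:
            v = block[ct].to_numpy(float)
            sd = float(v.std(ddof=1)) if n > 1 else 0.0
            rows.append(
                {
                    "stratum": label,
                    "cell_type": ct,
                    "mean": float(v.mean()),
                    "sd": sd,
                    "se": sd / np.sqrt(n) if n > 1 else 0.0,
                    "n": n,
                    "se_undefined": n < 2,
                }
            )
    return pd.DataFrame(rows)


def composition_diff(
    fractions: pd.DataFrame,
    metadata: pd.DataFrame,
    stratum_key: str,
    stratum_a: str,
    stratum_b: str,
) -> pd.Series:
    """Per-cell-type mean(a) - mean(b) in percentage points (fractions x 100)."""
    md = metadata.loc[fractions.index]
    a = fractions[md[stratum_key] == stratum_a]
    b = fractions[md[stratum_key] == stratum_b]
    if a.empty or b.empty:
        raise ValueError(
            f"stratum {stratum_a if a.empty else stratum_b!r} has no samples"
        )
    return (a.mean(axis=0) - b.mean(axis=0)) * 100.0
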