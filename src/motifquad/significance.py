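"""Motif significance: per-class z-scores against the random ensemble.

For class ``i`` with original count ``C_i`` and random-ensemble mean
``mu_i`` and population standard deviation ``sigma_i`` (a class absent
from a random network counts 0 there),

    z_i = (C_i - mu_i) / sigma_i.

Large positive z marks a motif, large negative z an anti-motif.  A
class whose count never varies across the ensemble has ``sigma_i = 0``
and its z is reported as undefined rather than infinite.  Only classes
present in the original network are reported; the frozen registry
already excluded novel random-network classes from the censuses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from io import StringIO
from pathlib import Path
from typing import Optional, Sequence, Union

from .canonical import ClassRegistry
from .esu import Census


@dataclass
class MotifRow:
    class_id: int
    canonical_label: str
    original_count: int
    random_mean: float
    random_sd: float
    z: Optional[float]  # None when random_sd == 0


@dataclass
class MotifReport:
    """Rows sorted by descending z; undefined-z rows last (by class id)."""

    rows: list[MotifRow]
    n_random: int

    def to_tsv(self) -> str:
        buf = StringIO()
        buf.write("class_id\tcanonical_label\tC\tmean\tsd\tz\n")
        for r in self.rows:
            z = "NA" if r.z is None else f"{r.z:.6g}"
            buf.write(f"{r.class_id}\t{r.canonical_label}\t{r.original_count}\t"
                      f"{r.random_mean:.6g}\t{r.random_sd:.6g}\t{z}\n")
        return buf.getvalue()

    def write_tsv(self, path: Union[str, Path]) -> None:
        Path(path).write_text(self.to_tsv())

    def to_dataframe(self):
        """Report as a pandas DataFrame (NaN for undefined z)."""
        import pandas as pd

        return pd.DataFrame(
            [(r.class_id, r.canonical_label, r.original_count,
              r.random_mean, r.random_sd,
              math.nan if r.z is None else r.z) for r in self.rows],
            columns=["class_id", "canonical_label", "C", "mean", "sd", "z"])


def z_scores(original: Census, randoms: Sequence[Census],
             registry: ClassRegistry) -> MotifReport:
    """Score every original-network class against the random censuses.

    Mean and SD are taken over exactly ``len(randoms)`` values with the
    population (divide-by-r) convention.
    """
    r = len(randoms)
    if r < 1:
        raise ValueError("at least one random census is required")
    rows: list[MotifRow] = []
    for cid in sorted(original.counts):
        c = original.counts[cid]
        values = [rc.counts.get(cid, 0) for rc in randoms]
        mu = sum(values) / r
        var = sum((v - mu) ** 2 for v in values) / r
        sd = math.sqrt(var)
        z = (c - mu) / sd if sd > 0 else None
        rows.append(MotifRow(class_id=cid,
                             canonical_label=registry.record(cid).canonical_label,
                             original_count=c, random_mean=mu, random_sd=sd, z=z))
    rows.sort(key=lambda r: (r.z is None, -(r.z if r.z is not None else 0.0),
                             r.class_id))
    return MotifReport(rows=rows, n_random=r)
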