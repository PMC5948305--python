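"""Alpha-diversity calculators for quantified OTU profiles.

Computed on integer-rounded consensus copy numbers after decontamination
and LOD filtering, i.e. on the community the pipeline actually reports.
Conventions follow the mothur defaults: bias-corrected Chao1, Shannon with
natural log, and Simpson as the unbiased dominance index
``D = sum n_i(n_i-1) / (N(N-1))`` (the complement ``1-D`` is also emitted).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Mapping

from .errors import PipelineError


def _validated(counts: Mapping[str, int]) -> dict[str, int]:
    if not counts:
        raise PipelineError("undefined diversity: empty community")
    out = {}
    for otu, n in counts.items():
        if not isinstance(n, (int,)) or isinstance(n, bool):
            raise PipelineError(f"counts must be integers, got {n!r} for {otu}")
        if n <= 0:
            raise PipelineError(f"counts must be positive, got {n} for {otu}")
        out[otu] = n
    return out


def chao1(counts: Mapping[str, int]) -> float:
    """Bias-corrected Chao1 richness estimate.

    ``S_obs + f1(f1-1) / (2(f2+1))`` where f1 and f2 are the numbers of
    singleton and doubleton OTUs.  With no singletons the estimate equals
    the observed richness.
    """
    counts = _validated(counts)
    sobs = len(counts)
    f1 = sum(1 for n in counts.values() if n == 1)
    f2 = sum(1 for n in counts.values() if n == 2)
    return sobs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def shannon(counts: Mapping[str, int]) -> float:
    """Shannon entropy ``H = -sum p_i ln p_i`` (natural log)."""
    counts = _validated(counts)
    total = sum(counts.values())
    return -sum((n / total) * math.log(n / total) for n in counts.values())


def simpson(counts: Mapping[str, int]) -> float:
    """Simpson dominance ``D = sum n_i(n_i-1) / (N(N-1))``.

    The probability that two individuals drawn without replacement belong
    to the same OTU; 1 for a single-OTU community, near 0 for very even
    ones.  Requires at least two individuals.
    """
    counts = _validated(counts)
    total = sum(counts.values())
    if total < 2:
        raise PipelineError("Simpson index needs at least 2 individuals")
    return sum(n * (n - 1) for n in counts.values()) / (total * (total - 1))


@dataclass(frozen=True)
class DiversitySummary:
    """Per-sample alpha-diversity summary shown in the report."""

    sobs: int
    chao1: float
    shannon: float
    simpson: float
    simpson_complement: float

    def to_dict(self) -> dict:
        return asdict(self)


def summarize(counts: Mapping[str, int]) -> DiversitySummary:
    """Compute all alpha-diversity indices for one community."""
    d = simpson(counts)
    return DiversitySummary(
        sobs=len(_validated(counts)),
        chao1=chao1(counts),
        shannon=shannon(counts),
        simpson=d,
        simpson_complement=1.0 - d,
    )
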