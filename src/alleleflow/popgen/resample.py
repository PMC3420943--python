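"""In-silico diploid resampling of expression-inferred genotypes.

Each individual's genotype at a locus is only known up to its expressed
allele-group set.  A diploid genotype compatible with that set is drawn
per replicate and Weir-Cockerham theta recomputed, propagating genotype
uncertainty into the F_ST estimate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .fst import Theta, wc_fst
from .records import IndividualRecord, group_records

logger = logging.getLogger(__name__)

DEFAULT_N_REPS = 100


def resample_diploid_genotype(
    record: IndividualRecord, locus: str, rng: np.random.Generator
) -> tuple[str, str] | None:
    """Draw one diploid genotype compatible with the expressed set.

    One expressed group implies a homozygote; two imply one copy of each;
    more than two are sampled uniformly without replacement.  An empty
    expressed set returns ``None`` (the individual is excluded at this
    locus and the exclusion logged).
    """
    expressed = sorted(record.expressed_at(locus))
    if not expressed:
        logger.info(
            "individual %s has no expressed groups at %s; excluded",
            record.id,
            locus,
        )
        return None
    if len(expressed) == 1:
        return (expressed[0], expressed[0])
    if len(expressed) == 2:
        return (expressed[0], expressed[1])
    pick = rng.choice(len(expressed), size=2, replace=False)
    pair = sorted(expressed[i] for i in pick)
    return (pair[0], pair[1])


@dataclass(frozen=True)
class FstEstimate:
    """Replicate distribution of resampled theta at one locus."""

    locus: str
    grouping: str
    replicates: tuple[float, ...]
    mean: float
    se: float
    n_reps: int
    flags: tuple[str, ...] = ()

    @property
    def inestimable(self) -> bool:
        return "inestimable" in self.flags


def resampled_fst(
    records: Sequence[IndividualRecord],
    locus: str,
    grouping: str = "species",
    n_reps: int = DEFAULT_N_REPS,
    seed: int = 0,
) -> FstEstimate:
    """Resample genotypes ``n_reps`` times and summarise theta.

    Replicate r uses the RNG stream seeded ``[seed, r]`` so every draw is
    attributable to the master seed.  Loci genotypable in fewer than two
    groups yield an inestimable result (flag, NaN mean) rather than an
    exception.  Replicates where theta is undefined (e.g. monomorphic
    draws) are dropped from the summary and flagged.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    groups = group_records(list(records), grouping)
    genotypable = {
        name: [r for r in recs if r.expressed_at(locus)]
        for name, recs in groups.items()
    }
    genotypable = {k: v for k, v in genotypable.items() if v}
    if len(genotypable) < 2:
        return FstEstimate(
            locus=locus,
            grouping=grouping,
            replicates=(),
            mean=math.nan,
            se=math.nan,
            n_reps=n_reps,
            flags=("inestimable",),
        )

    flags: set[str] = set()
    values: list[float] = []
    for rep in range(n_reps):
        rng = np.random.default_rng([seed, rep])
        drawn = {
            name: [
                g
                for rec in recs
                if (g := resample_diploid_genotype(rec, locus, rng)) is not None
            ]
            for name, recs in genotypable.items()
        }
        theta: Theta = wc_fst(drawn)
        if theta.flag is not None:
            flags.add(f"replicate_{theta.flag}")
        values.append(theta.value)

    finite = [v for v in values if not math.isnan(v)]
    if finite:
        mean = float(np.mean(finite))
        se = (
            float(np.std(finite, ddof=1) / math.sqrt(len(finite)))
            if len(finite) > 1
            else 0.0
        )
    else:
        mean = math.nan
        se = math.nan
        flags.add("inestimable")
    return FstEstimate(
        locus=locus,
        grouping=grouping,
        replicates=tuple(values),
        mean=mean,
        se=se,
        n_reps=n_reps,
        flags=tuple(sorted(flags)),
    )
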