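"""Per-sample alpha diversity and nonparametric richness estimation.

Reported indices: observed OTUs (S_obs), Shannon entropy H (natural log
by default, matching vegan), Simpson's index of diversity 1-D, Chao1
(classic and bias-corrected) and the abundance-based coverage estimator
ACE with the standard rare/abundant cut at 10 reads.  Estimation is
delegated to scikit-bio's alpha-diversity routines.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio.diversity import alpha as skbio_alpha

from cooccur.exact_cluster import OtuTable
from cooccur.io_formats import SampleManifest

logger = logging.getLogger(__name__)

DEFAULT_RARE_THRESHOLD = 10


@dataclass(frozen=True, slots=True)
class DiversityProfile:
    """Alpha-diversity estimates of one sample.

    `ace` is NaN when undefined (every rare taxon a singleton, so the
    coverage estimate is zero).
    """

    sample_id: str
    n_reads: int
    observed_otus: int
    shannon: float
    simpson_1mD: float
    chao1: float
    chao1_bias_corrected: float
    ace: float
    rare_threshold: int = DEFAULT_RARE_THRESHOLD


def alpha_diversity(
    counts,
    rare_threshold: int = DEFAULT_RARE_THRESHOLD,
    sample_id: str = "",
    shannon_base: float = math.e,
) -> DiversityProfile:
    """Estimate all alpha-diversity indices from one count vector.

    Zero-count entries are dropped; at least one read is required.
    Chao1 classic uses S_obs + F1^2/(2 F2) (F1(F1-1)/2 when F2 = 0);
    the bias-corrected form divides by 2(F2+1).
    """
    arr = np.asarray(counts, dtype=np.int64)
    if (arr < 0).any():
        raise ValueError("negative counts")
    arr = arr[arr > 0]
    n = int(arr.sum())
    if n == 0:
        raise ValueError("all counts are zero; diversity undefined")

    try:
        ace = float(skbio_alpha.ace(arr, rare_threshold=rare_threshold))
    except ValueError:
        logger.warning(
            "sample %r: all rare taxa are singletons; ACE undefined", sample_id
        )
        ace = float("nan")

    return DiversityProfile(
        sample_id=sample_id,
        n_reads=n,
        observed_otus=int(skbio_alpha.sobs(arr)),
        shannon=float(skbio_alpha.shannon(arr, base=shannon_base)),
        simpson_1mD=float(skbio_alpha.simpson(arr)),
        chao1=float(skbio_alpha.chao1(arr, bias_corrected=False)),
        chao1_bias_corrected=float(skbio_alpha.chao1(arr, bias_corrected=True)),
        ace=ace,
        rare_threshold=rare_threshold,
    )


def diversity_table(
    table: OtuTable,
    manifest: SampleManifest | None = None,
    rare_threshold: int = DEFAULT_RARE_THRESHOLD,
    shannon_base: float = math.e,
) -> pd.DataFrame:
    """Alpha diversity of every sample column of an OTU table.

    When a manifest is given, subject/site/timepoint/group columns are
    joined in for downstream group comparisons.
    """
    rows = []
    for sample_id in table.sample_ids:
        col = table.counts[sample_id].to_numpy()
        if col.sum() == 0:
            logger.warning("sample %r has zero reads; skipped", sample_id)
            continue
        prof = alpha_diversity(
            col, rare_threshold=rare_threshold, sample_id=sample_id,
            shannon_base=shannon_base,
        )
        rows.append(
            {
                "sample_id": prof.sample_id,
                "n_reads": prof.n_reads,
                "observed_otus": prof.observed_otus,
                "shannon": prof.shannon,
                "simpson_1mD": prof.simpson_1mD,
                "chao1": prof.chao1,
                "chao1_bias_corrected": prof.chao1_bias_corrected,
                "ace": prof.ace,
            }
        )
    out = pd.DataFrame(rows)
    if manifest is not None and not out.empty:
        meta = manifest.frame[["sample_id", "subject_id", "site", "timepoint", "group"]]
        out = out.merge(meta, on="sample_id", how="left")
    return out


DIVERSITY_INDICES = (
    "observed_otus",
    "shannon",
    "simpson_1mD",
    "chao1",
    "chao1_bias_corrected",
    "ace",
)
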