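"""Tissue expression calls and expression-specificity z-scores.

A gene is called expressed in a tissue when its normalized expression (CPM)
is at least 0.5 in strictly more than 90% of that tissue's samples.  The
specificity of gene i in tissue t standardizes the tissue mean against the
gene's mean and standard deviation across all included tissues:

    z_E(i, t) = (E(i, t) - <E(i)>) / delta_E(i)

delta_E uses the sample (n-1) standard deviation; this convention is pinned
by the unit tests.  Brain regions may be pooled into a single "brain" column
(mean of region means) before scoring — pooling then scoring is not the same
as scoring then averaging, so the order is fixed here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CPM_THRESHOLD_DEFAULT = 0.5
SAMPLE_FRACTION_DEFAULT = 0.9


def _tissue_groups(matrix: pd.DataFrame, sample_tissue_map) -> dict[str, list[str]]:
    mapping = dict(sample_tissue_map) if not isinstance(sample_tissue_map, dict) else sample_tissue_map
    missing = [s for s in matrix.columns if s not in mapping]
    if missing:
        raise ValueError(f"samples without a tissue assignment: {missing[:10]}")
    groups: dict[str, list[str]] = {}
    for sample in matrix.columns:
        groups.setdefault(mapping[sample], []).append(sample)
    for tissue, samples in groups.items():
        if not samples:
            raise ValueError(f"tissue {tissue!r} has zero samples")
    return groups


def call_expressed(
    matrix: pd.DataFrame,
    sample_tissue_map,
    cpm_threshold: float = CPM_THRESHOLD_DEFAULT,
    sample_fraction: float = SAMPLE_FRACTION_DEFAULT,
) -> pd.DataFrame:
    """Boolean gene x tissue matrix of expressed calls.

    expressed(i, t) is true iff the fraction of tissue-t samples with
    value >= cpm_threshold is strictly greater than sample_fraction
    ("over 90%": exactly 90% does not qualify).
    """
    groups = _tissue_groups(matrix, sample_tissue_map)
    calls = {}
    for tissue in sorted(groups):
        sub = matrix[groups[tissue]]
        frac = (sub >= cpm_threshold).sum(axis=1) / sub.shape[1]
        calls[tissue] = frac > sample_fraction
    return pd.DataFrame(calls, index=matrix.index)


def tissue_means(
    matrix: pd.DataFrame,
    sample_tissue_map,
    log_transform: bool = False,
) -> pd.DataFrame:
    """Arithmetic per-tissue means of per-sample values (optional log2(x+1) first)."""
    groups = _tissue_groups(matrix, sample_tissue_map)
    values = np.log2(matrix + 1.0) if log_transform else matrix
    return pd.DataFrame(
        {tissue: values[samples].mean(axis=1) for tissue, samples in sorted(groups.items())},
        index=matrix.index,
    )


def specificity_z(E: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Expression-specificity z-scores from a gene x tissue matrix of means.

    Rows with zero variance across tissues (constant profile) get z = 0 in
    every tissue and are listed in ``result.attrs["constant_genes"]``.
    Requires at least two tissue columns.
    """
    if E.shape[1] < 2:
        raise ValueError("specificity needs at least two tissues")
    mean = E.mean(axis=1)
    sd = E.std(axis=1, ddof=ddof)
    constant = sd == 0
    safe_sd = sd.mask(constant, 1.0)
    z = E.sub(mean, axis=0).div(safe_sd, axis=0)
    z.loc[constant] = 0.0
    z.attrs["constant_genes"] = list(E.index[constant])
    return z


def region_specificity(E_regions: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Specificity z-scores restricted to brain regions (same contract as
    :func:`specificity_z` on the region-restricted matrix)."""
    return specificity_z(E_regions, ddof=ddof)


def pool_tissues(
    E: pd.DataFrame,
    members: list[str],
    pooled_name: str = "brain",
) -> pd.DataFrame:
    """Pool several tissue columns into one (mean of the per-tissue means).

    This pre-aggregation is applied *before* scoring; the pooled column
    replaces its members.  Used to compare brain (all regions combined)
    against the other tissues.
    """
    missing = [m for m in members if m not in E.columns]
    if missing:
        raise ValueError(f"tissues not in matrix: {missing}")
    pooled = E[members].mean(axis=1)
    rest = E.drop(columns=members)
    out = rest.copy()
    out[pooled_name] = pooled
    return out


def positive_brain_specific(zE: pd.DataFrame, brain_col: str = "brain") -> set[str]:
    """Genes with positive brain specificity: z_E(i, brain) > 0."""
    if brain_col not in zE.columns:
        raise ValueError(f"no {brain_col!r} column in specificity matrix")
    return set(zE.index[zE[brain_col] > 0])


def load_expression(matrix_path, tissue_map_path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Load a gene x sample TSV and a two-column sample -> tissue TSV."""
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0)
    tmap = pd.read_csv(tissue_map_path, sep="\t", header=None, names=["sample", "tissue"])
    return matrix, dict(zip(tmap["sample"], tmap["tissue"]))
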