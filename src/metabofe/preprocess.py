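"""Metabolome preprocessing: total-intensity normalization and HMDB filtering.

The pipeline starts from a birds x features intensity table (one per ion
mode).  Peak picking, alignment and database matching happen upstream of this
package; here each sample is normalized to its total spectral intensity (every
row divided by its own sum, so row sums become 1) and features without an HMDB
accession are dropped.  The fixed order is normalize -> annotate.  A log10
transform is provided for heatmap-style display only; statistics and the
genetic model run on the normalized linear scale by default (a scale switch is
exposed where it matters).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import DegenerateSampleError, EmptyPanelError, InputError, TransformError

logger = logging.getLogger(__name__)

__all__ = [
    "MetaboliteMatrix",
    "TotalIntensityNormalizer",
    "normalize_total_intensity",
    "annotate_and_filter",
    "log10_display",
]


@dataclass
class MetaboliteMatrix:
    """Birds x features intensity matrix for one ion mode.

    Attributes
    ----------
    intensities : pandas.DataFrame
        Rows indexed by bird id, columns by feature id; nonnegative.
    ion_mode : str
        ``"positive"`` or ``"negative"``.
    hmdb_ids : dict
        feature id -> HMDB accession (may be partial before filtering).
    normalized : bool
        Whether rows have been normalized to total intensity.
    """

    intensities: pd.DataFrame
    ion_mode: str
    hmdb_ids: dict = field(default_factory=dict)
    normalized: bool = False

    def __post_init__(self):
        if self.ion_mode not in ("positive", "negative"):
            raise InputError(f"ion_mode must be 'positive' or 'negative', got {self.ion_mode!r}")
        values = self.intensities.to_numpy(dtype=float)
        if np.any(values < 0):
            raise InputError("metabolite intensities must be nonnegative")

    @property
    def bird_ids(self) -> list[str]:
        return [str(b) for b in self.intensities.index]

    @property
    def feature_ids(self) -> list[str]:
        return [str(f) for f in self.intensities.columns]

    def to_tsv(self, path) -> None:
        self.intensities.rename_axis("bird_id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, ion_mode: str, annotation_csv=None, normalized: bool = False):
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        hmdb = {}
        if annotation_csv is not None:
            ann = pd.read_csv(annotation_csv, dtype=str)
            hmdb = dict(zip(ann["feature_id"], ann["hmdb_id"]))
        return cls(intensities=df, ion_mode=ion_mode, hmdb_ids=hmdb, normalized=normalized)

    def write_annotation(self, path) -> None:
        pd.DataFrame(
            {"feature_id": list(self.hmdb_ids), "hmdb_id": list(self.hmdb_ids.values())}
        ).to_csv(path, index=False)


class TotalIntensityNormalizer(TransformerMixin, BaseEstimator):
    """Row-stochastic scaling: each sample divided by its total intensity.

    Stateless (fit is a validation pass); kept as a transformer so it can sit
    in an sklearn pipeline.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise InputError("expected a 2-D intensity matrix")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        totals = X.sum(axis=1)
        bad = np.flatnonzero(totals <= 0)
        if bad.size:
            raise DegenerateSampleError(
                f"samples with zero total intensity at rows {bad.tolist()}", bird_ids=bad
            )
        return X / totals[:, None]


def normalize_total_intensity(matrix: MetaboliteMatrix) -> MetaboliteMatrix:
    """Normalize every bird's spectrum to its total intensity (row sums 1)."""
    if matrix.normalized:
        raise InputError("matrix is already normalized")
    values = matrix.intensities.to_numpy(dtype=float)
    totals = values.sum(axis=1)
    bad = np.flatnonzero(totals <= 0)
    if bad.size:
        ids = [matrix.bird_ids[i] for i in bad]
        raise DegenerateSampleError(f"all-zero samples: {ids}", bird_ids=ids)
    out = matrix.intensities.div(totals, axis=0)
    return MetaboliteMatrix(
        intensities=out, ion_mode=matrix.ion_mode, hmdb_ids=dict(matrix.hmdb_ids), normalized=True
    )


def annotate_and_filter(matrix: MetaboliteMatrix, mapping: dict) -> MetaboliteMatrix:
    """Keep only features with an HMDB accession, preserving column order."""
    mapping = {str(k): v for k, v in mapping.items()}
    keep = [f for f in matrix.feature_ids if f in mapping and mapping[f]]
    dropped = [f for f in matrix.feature_ids if f not in keep]
    if not keep:
        raise EmptyPanelError(
            f"no {matrix.ion_mode}-mode feature has an HMDB annotation; empty panel"
        )
    logger.info(
        "%s mode: retained %d/%d annotated features (dropped %d)",
        matrix.ion_mode,
        len(keep),
        len(matrix.feature_ids),
        len(dropped),
    )
    if dropped:
        logger.debug("dropped unannotated features: %s", dropped)
    return MetaboliteMatrix(
        intensities=matrix.intensities[keep],
        ion_mode=matrix.ion_mode,
        hmdb_ids={f: mapping[f] for f in keep},
        normalized=matrix.normalized,
    )


def log10_display(matrix: MetaboliteMatrix) -> pd.DataFrame:
    """Element-wise log10 for heatmap-style reporting (display only)."""
    values = matrix.intensities.to_numpy(dtype=float)
    if np.any(values <= 0):
        raise TransformError("log10 display requires strictly positive intensities")
    return pd.DataFrame(
        np.log10(values), index=matrix.intensities.index, columns=matrix.intensities.columns
    )
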