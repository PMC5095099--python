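"""The genes x samples expression container.

An :class:`ExpressionMatrix` is a validated, immutable-shaped wrapper around a
real-valued matrix of expression intensities with gene and sample identifiers,
optionally tagged with a condition-group label.  Rows are genes, columns are
samples (the microarray convention); estimator classes that follow the
scikit-learn convention receive the transpose (samples x features) and the
conversion helpers here keep the two orientations straight.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError

__all__ = ["ExpressionMatrix"]


@dataclass
class ExpressionMatrix:
    """Expression intensities for ``n_genes`` genes over ``n_samples`` samples.

    Parameters
    ----------
    gene_ids : sequence of str
        Unique gene (probe/transcript) identifiers, one per row.
    sample_ids : sequence of str
        Unique sample identifiers, one per column.
    values : ndarray of shape (n_genes, n_samples)
        Finite real expression values (arbitrary units).
    group : str, optional
        Condition-group label (e.g. a temperature group).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    group: Optional[str] = None

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise InvalidInputError("values must be a 2-D genes x samples matrix")
        n_g, n_s = self.values.shape
        if n_g == 0 or n_s == 0:
            raise InvalidInputError("expression matrix must be non-empty")
        if len(self.gene_ids) != n_g:
            raise InvalidInputError(
                f"{len(self.gene_ids)} gene ids for {n_g} matrix rows"
            )
        if len(self.sample_ids) != n_s:
            raise InvalidInputError(
                f"{len(self.sample_ids)} sample ids for {n_s} matrix columns"
            )
        if len(set(self.gene_ids)) != n_g:
            raise InvalidInputError("duplicated gene ids")
        if len(set(self.sample_ids)) != n_s:
            raise InvalidInputError("duplicated sample ids")
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("expression values must all be finite")

    # -- shape ------------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise InvalidInputError(f"gene {gene!r} not present") from None

    # -- conversion -------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Return a genes x samples :class:`pandas.DataFrame`."""
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, group: Optional[str] = None
                   ) -> "ExpressionMatrix":
        """Build from a genes x samples DataFrame (index = genes)."""
        return cls(
            gene_ids=list(map(str, frame.index)),
            sample_ids=list(map(str, frame.columns)),
            values=frame.to_numpy(dtype=np.float64),
            group=group,
        )

    def with_values(self, values: np.ndarray,
                    sample_ids: Optional[Sequence[str]] = None
                    ) -> "ExpressionMatrix":
        """Copy, replacing the value matrix (and optionally the sample ids)."""
        return replace(
            self,
            values=np.asarray(values, dtype=np.float64),
            sample_ids=list(sample_ids) if sample_ids is not None
            else list(self.sample_ids),
            gene_ids=list(self.gene_ids),
        )
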