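"""Response-gene calling from differential-expression tables.

Differentially expressed genes from a late-vs-early contrast are reduced
to a high-confidence "response gene" set by five rules: statistical
significance, a minimum expression level, a minimum fold change, limited
replicate variability, and cross-donor consistency. Retained genes are
annotated as transcription factors (via a DoRothEA-like list), metabolic
genes (via a metabolic-reconstruction gene list), or other.

Expected table schema (one row per gene):

====================  =====================================================
column                meaning
====================  =====================================================
gene                  identifier
log2fc                contrast log2 fold change
pvalue, adj_pvalue    raw and BH-adjusted p-values
mean_tpm_<cond>       mean TPM per compared condition (two columns)
rel_sem_<cond>        SEM / |mean| of expression per condition
log2fc_donor<i>       per-donor log2 fold change
sig_donor<i>          per-donor significance flag (bool)
====================  =====================================================
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

__all__ = ["ResponseGeneSet", "ResponseGeneFilter", "call_response_genes",
           "annotate_gene_classes"]


@dataclass
class ResponseGeneSet:
    """Retained response genes with direction and class counts."""

    genes: pd.DataFrame  # columns: gene, direction, (class after annotation)
    counts: dict

    def __len__(self) -> int:
        return len(self.genes)

    def direction_of(self, gene: str) -> str:
        row = self.genes.loc[self.genes["gene"] == gene, "direction"]
        if row.empty:
            raise KeyError(gene)
        return row.iloc[0]

    @property
    def up(self) -> list:
        return self.genes.loc[self.genes["direction"] == "up", "gene"].tolist()

    @property
    def down(self) -> list:
        return self.genes.loc[self.genes["direction"] == "down", "gene"].tolist()


class ResponseGeneFilter(BaseEstimator):
    """Five-rule response-gene filter over a DE table.

    A gene is retained iff it is (a) significant (p < ``p_threshold`` and
    adjusted p < ``adj_p_threshold``), (b) expressed (max condition mean
    TPM >= ``tpm_threshold``), (c) strongly changed (|log2FC| >=
    ``fc_threshold``), (d) reproducible (relative SEM <=
    ``rel_sem_threshold`` in every condition), and (e) donor-consistent
    (significant with the contrast's sign in >= ``min_consistent_donors``
    donors).

    The filter is monotone: relaxing any threshold never drops a
    previously retained gene.
    """

    def __init__(self, tpm_threshold: float = 2.0, fc_threshold: float = 1.0,
                 rel_sem_threshold: float = 0.5, min_consistent_donors: int = 2,
                 p_threshold: float = 0.05, adj_p_threshold: float = 0.1):
        self.tpm_threshold = tpm_threshold
        self.fc_threshold = fc_threshold
        self.rel_sem_threshold = rel_sem_threshold
        self.min_consistent_donors = min_consistent_donors
        self.p_threshold = p_threshold
        self.adj_p_threshold = adj_p_threshold

    @staticmethod
    def _columns(records: pd.DataFrame, prefix: str) -> list:
        cols = [c for c in records.columns if c.startswith(prefix)]
        if not cols:
            raise ValueError(f"no '{prefix}*' columns in DE table")
        return cols

    def fit(self, records: pd.DataFrame, y=None):
        for col in ("gene", "log2fc", "pvalue", "adj_pvalue"):
            if col not in records.columns:
                raise ValueError(f"DE table lacks required column '{col}'")
        tpm_cols = self._columns(records, "mean_tpm_")
        sem_cols = self._columns(records, "rel_sem_")
        fc_cols = sorted(self._columns(records, "log2fc_donor"))
        sig_cols = sorted(self._columns(records, "sig_donor"))
        donor_block = records[fc_cols + sig_cols]
        if donor_block.isna().any(axis=None):
            bad = records.loc[donor_block.isna().any(axis=1), "gene"].iloc[0]
            raise ValueError(f"missing per-donor fields for gene '{bad}'")

        significant = ((records["pvalue"] < self.p_threshold)
                       & (records["adj_pvalue"] < self.adj_p_threshold))
        expressed = records[tpm_cols].max(axis=1) >= self.tpm_threshold
        changed = records["log2fc"].abs() >= self.fc_threshold
        stable = (records[sem_cols] <= self.rel_sem_threshold).all(axis=1)
        sign = np.sign(records["log2fc"])
        consistent_count = sum(
            (np.sign(records[fc]) == sign) & records[sig].astype(bool)
            for fc, sig in zip(fc_cols, sig_cols)
        )
        consistent = consistent_count >= self.min_consistent_donors

        keep = significant & expressed & changed & stable & consistent
        retained = records.loc[keep, ["gene", "log2fc"]].copy()
        retained["direction"] = np.where(retained["log2fc"] > 0, "up", "down")
        self.rule_mask_ = pd.DataFrame({
            "significant": significant, "expressed": expressed,
            "changed": changed, "stable": stable, "consistent": consistent,
        }, index=records.index)
        self.response_genes_ = retained[["gene", "direction"]].reset_index(drop=True)
        return self

    def transform(self, records: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "response_genes_")
        return records[records["gene"].isin(self.response_genes_["gene"])]


def call_response_genes(records: pd.DataFrame, tpm_threshold: float = 2.0,
                        fc_threshold: float = 1.0,
                        rel_sem_threshold: float = 0.5,
                        min_consistent_donors: int = 2,
                        tf_list=None, metabolic_list=None) -> ResponseGeneSet:
    """Apply the five-rule filter; optionally annotate gene classes."""
    filt = ResponseGeneFilter(
        tpm_threshold=tpm_threshold, fc_threshold=fc_threshold,
        rel_sem_threshold=rel_sem_threshold,
        min_consistent_donors=min_consistent_donors,
    ).fit(records)
    genes = filt.response_genes_.copy()
    if tf_list is not None or metabolic_list is not None:
        classes = annotate_gene_classes(genes["gene"], tf_list or (),
                                        metabolic_list or ())
        genes["class"] = genes["gene"].map(classes)
        counts = genes.groupby(["direction", "class"]).size().to_dict()
    else:
        counts = genes["direction"].value_counts().to_dict()
    return ResponseGeneSet(genes=genes, counts=counts)


def annotate_gene_classes(genes, tf_list, metabolic_list) -> dict:
    """Label each gene TF, metabolic or other (TF takes precedence)."""
    tfs = set(tf_list)
    metabolic = set(metabolic_list)
    out = {}
    for g in genes:
        if g in tfs:
            out[g] = "TF"
        elif g in metabolic:
            out[g] = "metabolic"
        else:
            out[g] = "other"
    return out
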