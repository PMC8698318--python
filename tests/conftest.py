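import numpy as np
import pandas as pd
import pytest

from osteostage import (ExpressionSimConfig, call_response_genes,
                        simulate_expression, zscore_genes)
from osteostage.regulons import RegulonInference


@pytest.fixture(scope="session")
def expression_study():
    """One full expression simulation + inference run shared across tests."""
    cfg = ExpressionSimConfig(seed=3)
    tpm, de, prior_df, tfs, metabolic, truth = simulate_expression(cfg)
    response = call_response_genes(de, tf_list=tfs, metabolic_list=metabolic)
    z, _ = zscore_genes(np.log2(tpm + 1.0))
    prior = {reg: set(sub["target"])
             for reg, sub in prior_df.groupby("regulator")}
    est = RegulonInference().fit(z, response, prior)
    return {
        "config": cfg, "tpm": tpm, "de": de, "prior": prior,
        "tf_list": tfs, "metabolic": metabolic, "truth": truth,
        "response": response, "z": z, "est": est,
    }


def make_toy_de_table() -> pd.DataFrame:
    """Six genes: five each violating exactly one filter rule, one clean."""
    def row(gene, **kw):
        base = dict(
            gene=gene, log2fc=2.0, pvalue=0.001, adj_pvalue=0.01,
            mean_tpm_first=10.0, mean_tpm_last=40.0,
            rel_sem_first=0.1, rel_sem_last=0.1,
            log2fc_donor1=2.1, sig_donor1=True,
            log2fc_donor2=1.9, sig_donor2=True,
            log2fc_donor3=2.0, sig_donor3=True,
        )
        base.update(kw)
        return base

    return pd.DataFrame([
        row("clean"),
        row("not_significant", pvalue=0.2, adj_pvalue=0.5),
        row("low_expression", mean_tpm_first=1.5, mean_tpm_last=1.9),
        row("small_fold_change", log2fc=0.5, log2fc_donor1=0.5,
            log2fc_donor2=0.5, log2fc_donor3=0.5),
        row("high_variability", rel_sem_last=0.8),
        row("donor_inconsistent", sig_donor2=False, sig_donor3=False),
    ])
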