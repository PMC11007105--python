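import numpy as np
import pytest

from mrkit.gwas_io import GwasRecord, HarmonizedSet


@pytest.fixture
def make_harmonized():
    """Factory for a HarmonizedSet built directly from effect arrays."""

    def _make(
        beta_exp,
        beta_out,
        se_out,
        se_exp=None,
        eaf=None,
        n_exp=10000,
        n_out=50000,
    ) -> HarmonizedSet:
        beta_exp = np.asarray(beta_exp, dtype=float)
        beta_out = np.asarray(beta_out, dtype=float)
        se_out = np.asarray(se_out, dtype=float)
        J = beta_exp.size
        se_exp = (
            np.full(J, 1e-8) if se_exp is None else np.asarray(se_exp, dtype=float)
        )
        eaf = np.full(J, np.nan) if eaf is None else np.asarray(eaf, dtype=float)
        return HarmonizedSet(
            snp_ids=[f"rs{i}" for i in range(J)],
            beta_exp=beta_exp,
            se_exp=se_exp,
            eaf_exp=eaf,
            pval_exp=np.full(J, 1e-10),
            beta_out=beta_out,
            se_out=se_out,
            eaf_out=eaf.copy(),
            pval_out=np.full(J, 0.5),
            flipped=np.zeros(J, dtype=bool),
            n_exp=n_exp,
            n_out=n_out,
        )

    return _make


@pytest.fixture
def make_record():
    """Factory for a valid GwasRecord with overridable fields."""

    def _make(**kw) -> GwasRecord:
        base = dict(
            snp_id="rs1",
            effect_allele="A",
            other_allele="G",
            beta=0.1,
            se=0.02,
            pval=1e-9,
            eaf=0.3,
            n=10000,
        )
        base.update(kw)
        return GwasRecord(**base)

    return _make
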