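import pytest

from ivmr.harmonize import HarmonizedInstrument
from ivmr.sumstats import SummaryDataset, SummaryStatRecord


def make_record(
    snp_id="rs1",
    effect_allele="A",
    other_allele="G",
    beta=0.1,
    se=0.01,
    pval=1e-10,
    chrom="1",
    pos=1_000_000,
    eaf=0.3,
    n=100_000.0,
    **kwargs,
):
    return SummaryStatRecord(
        snp_id=snp_id,
        effect_allele=effect_allele,
        other_allele=other_allele,
        beta=beta,
        se=se,
        pval=pval,
        chrom=chrom,
        pos=pos,
        eaf=eaf,
        n=n,
        **kwargs,
    )


def make_dataset(records, trait_label="trait", trait_type="binary", n_default=None):
    return SummaryDataset(trait_label, trait_type, list(records), n_default=n_default)


@pytest.fixture
def three_instruments():
    """Hand-checkable set: ratios 0.4/0.5/0.6, IVW weights 25/100/25."""
    return [
        HarmonizedInstrument("rs1", 0.5, 0.01, 0.25, 0.05),
        HarmonizedInstrument("rs2", 0.4, 0.01, 0.24, 0.08),
        HarmonizedInstrument("rs3", 0.25, 0.01, 0.10, 0.05),
    ]


@pytest.fixture
def sumstats_tsv(tmp_path):
    """Well-formed 3-row exposure file in the canonical dialect."""
    path = tmp_path / "exposure.tsv"
    path.write_text(
        "snp\tchr\tpos\teffect_allele\tother_allele\teaf\tbeta\tse\tpval\tn\n"
        "rs1\t1\t1000000\tA\tG\t0.30\t0.10\t0.015\t2.5e-11\t100000\n"
        "rs2\t2\t2000000\tC\tT\t0.10\t-0.08\t0.012\t2.5e-11\t100000\n"
        "rs3\t3\t3000000\tG\tA\t0.45\t0.05\t0.008\t4.1e-10\t100000\n"
    )
    return path
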