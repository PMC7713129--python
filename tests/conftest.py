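import pandas as pd
import pytest

from dgvar import (
    AnnotationStore,
    GeneRoleTable,
    SimulationConfig,
    VariantAnnotation,
    generate_cohort,
    make_call,
)


def ann(
    chrom="chr1",
    pos=100,
    ref="A",
    alt="T",
    gene="TSG001",
    effect="stop_gained",
    clinvar_class="absent",
    condition=None,
    pop_af=0.0,
    inbreeding_pass=True,
    vqsr_pass=True,
    cadd=None,
    dbsnp=False,
    cosmic=False,
):
    """Shorthand annotation builder for unit fixtures."""
    return VariantAnnotation(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        gene=gene,
        effect=effect,
        canonical_effect=effect,
        clinvar_class=clinvar_class,
        clinvar_condition_is_cancer=condition,
        pop_af=pop_af,
        inbreeding_pass=inbreeding_pass,
        vqsr_pass=vqsr_pass,
        cadd_phred=cadd,
        dbsnp=dbsnp,
        cosmic=cosmic,
    )


def call(
    sample="P1",
    chrom="chr1",
    pos=100,
    ref="A",
    alt="T",
    qual=99.0,
    depth=60,
    alt_depth=30,
    genotype="het",
):
    return make_call(sample, chrom, pos, ref, alt, qual, depth, alt_depth, genotype)


@pytest.fixture
def roles():
    t = GeneRoleTable()
    t.set_role("TSG001", "TSG")
    t.set_role("TSG002", "TSG")
    t.set_role("ONC001", "oncogene")
    return t


@pytest.fixture
def store():
    return AnnotationStore()


@pytest.fixture(scope="session")
def cohort_bundle(tmp_path_factory):
    """A 24-patient synthetic bundle shared across integration tests.

    24 patients keep the per-patient recurrence of a unique variant (1/24)
    under the 5% cohort-recurrence cap, so planted recovery is exact.
    """
    out = tmp_path_factory.mktemp("bundle") / "cohort"
    config = SimulationConfig(seed=20240907, n_patients=24)
    bundle, truth = generate_cohort(config, out)
    return bundle, truth, config


def read_tsv(path):
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})
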