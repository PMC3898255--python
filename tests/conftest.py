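import textwrap

import numpy as np
import pytest

from degmotif.core_io import read_fasta, read_gff3
from degmotif.pipeline import PipelineConfig, run_discovery
from degmotif.synth import SynthConfig, simulate

# ---------------------------------------------------------------------------
# Handcrafted multi-isoform annotation on one 2 kb chromosome.
#
# geneA (+, 101-600 1-based): two isoforms
#   A.1 single exon, CDS 201-450            -> derived UTRs 101-200 / 451-600
#   A.2 exons 101-300 + 401-600, CDS 251-500 (split) -> intron 301-400
# geneB (-, 901-1400): explicit UTR features; 5'UTR on the high side
# geneC (+, 1501-1700): mRNA without CDS
# ---------------------------------------------------------------------------

TOY_GFF = textwrap.dedent(
    """\
    ##gff-version 3
    c1\ttest\tgene\t101\t600\t.\t+\t.\tID=geneA
    c1\ttest\tmRNA\t101\t600\t.\t+\t.\tID=geneA.1;Parent=geneA
    c1\ttest\texon\t101\t600\t.\t+\t.\tID=geneA.1.e1;Parent=geneA.1
    c1\ttest\tCDS\t201\t450\t.\t+\t.\tID=geneA.1.c1;Parent=geneA.1
    c1\ttest\tmRNA\t101\t600\t.\t+\t.\tID=geneA.2;Parent=geneA
    c1\ttest\texon\t101\t300\t.\t+\t.\tID=geneA.2.e1;Parent=geneA.2
    c1\ttest\texon\t401\t600\t.\t+\t.\tID=geneA.2.e2;Parent=geneA.2
    c1\ttest\tCDS\t251\t300\t.\t+\t.\tID=geneA.2.c1;Parent=geneA.2
    c1\ttest\tCDS\t401\t500\t.\t+\t.\tID=geneA.2.c2;Parent=geneA.2
    c1\ttest\tgene\t901\t1400\t.\t-\t.\tID=geneB
    c1\ttest\tmRNA\t901\t1400\t.\t-\t.\tID=geneB.1;Parent=geneB
    c1\ttest\texon\t901\t1400\t.\t-\t.\tID=geneB.1.e1;Parent=geneB.1
    c1\ttest\tCDS\t1001\t1300\t.\t-\t.\tID=geneB.1.c1;Parent=geneB.1
    c1\ttest\tfive_prime_UTR\t1301\t1400\t.\t-\t.\tID=geneB.1.u5;Parent=geneB.1
    c1\ttest\tthree_prime_UTR\t901\t1000\t.\t-\t.\tID=geneB.1.u3;Parent=geneB.1
    c1\ttest\tgene\t1501\t1700\t.\t+\t.\tID=geneC
    c1\ttest\tmRNA\t1501\t1700\t.\t+\t.\tID=geneC.1;Parent=geneC
    c1\ttest\texon\t1501\t1700\t.\t+\t.\tID=geneC.1.e1;Parent=geneC.1
    c1\ttest\tncRNA\t1801\t1900\t.\t+\t.\tID=sno1;ncrna_class=CD_box
    """
)


@pytest.fixture(scope="session")
def toy_paths(tmp_path_factory):
    d = tmp_path_factory.mktemp("toy")
    gff = d / "toy.gff3"
    gff.write_text(TOY_GFF)
    rng = np.random.default_rng(7)
    seq = "".join(rng.choice(list("ACGT"), size=2000))
    fa = d / "toy.fa"
    fa.write_text(">c1\n" + seq + "\n")
    return {"gff": gff, "fasta": fa}


@pytest.fixture(scope="session")
def toy_annotation(toy_paths):
    return read_gff3(toy_paths["gff"])


@pytest.fixture(scope="session")
def toy_genome(toy_paths):
    return read_fasta(toy_paths["fasta"])


# ---------------------------------------------------------------------------
# Default synthetic study bundle (seed 17) shared across the heavier tests.
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def bundle17():
    return simulate(SynthConfig(seed=17))


@pytest.fixture(scope="session")
def bundle17_paths(bundle17, tmp_path_factory):
    return bundle17.write(tmp_path_factory.mktemp("bundle17"))


@pytest.fixture(scope="session")
def bundle17_no_mispriming():
    return simulate(SynthConfig(seed=17, mispriming=None))


@pytest.fixture(scope="session")
def run17(bundle17_paths, tmp_path_factory):
    out = tmp_path_factory.mktemp("run17")
    config = PipelineConfig(
        genome=str(bundle17_paths["genome"]),
        gff=str(bundle17_paths["annotation"]),
        reads=str(bundle17_paths["ends"]),
        mirna_sites=str(bundle17_paths["mirna_sites"]),
        out_dir=str(out),
        render=False,
        seed=17,
    )
    return run_discovery(config)
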