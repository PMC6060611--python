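import numpy as np
import pysam
import pytest

from crackle.pipeline import run_pipeline
from crackle.simulate import (
    SimulationConfig,
    make_transcriptome,
    simulate_crac_reads,
    write_transcriptome,
)


def write_sam(path, records, contigs):
    """Write a SAM file from (qname, flag, contig, pos1, cigar, seq, tags) tuples."""
    header = {
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": name, "LN": length} for name, length in contigs.items()],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        names = list(contigs)
        for qname, flag, contig, pos1, cigar, seq, tags in records:
            aln = pysam.AlignedSegment(out.header)
            aln.query_name = qname
            aln.flag = flag
            aln.reference_id = names.index(contig)
            aln.reference_start = pos1 - 1
            aln.mapping_quality = 60
            aln.cigarstring = cigar
            aln.query_sequence = seq
            if tags:
                aln.set_tags(list(tags))
            out.write(aln)
    return path


@pytest.fixture
def sam_factory(tmp_path):
    def factory(records, contigs, name="reads.sam"):
        return write_sam(tmp_path / name, records, contigs)

    return factory


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A reduced-scale synthetic dataset shared by pipeline-level tests."""
    out = tmp_path_factory.mktemp("smallsim")
    config = SimulationConfig(
        seed=20,
        n_transcripts=20,
        n_planted_sites=60,
        n_sponge_sites=3,
        reads_per_replicate=12_000,
        control_reads=12_000,
    )
    tx = make_transcriptome(config)
    paths = write_transcriptome(tx, out)
    paths.update(simulate_crac_reads(config, tx, out))
    return {"config": config, "tx": tx, "paths": paths, "dir": out}


@pytest.fixture(scope="session")
def small_pipeline_result(small_dataset):
    paths = small_dataset["paths"]
    return run_pipeline(
        [paths["rep1"], paths["rep2"]],
        paths["control"],
        paths["fasta"],
        paths["gtf"],
        paths["expression"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
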