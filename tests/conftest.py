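import textwrap

import pytest

from bsinc.read_processing import BarcodeLibrary, ReadRecord


def write(path, content):
    path.write_text(textwrap.dedent(content))
    return path


@pytest.fixture
def tiny_reference(tmp_path):
    """Two single-contig genomes (1 kb, 2 kb) plus a 2-contig genome (0.3+0.7 kb)."""
    write(tmp_path / "a.fasta", f">c1\n{'A' * 1000}\n>c2\n{'C' * 2000}\n")
    write(tmp_path / "b.fasta", f">c3\n{'G' * 300}\n>c4\n{'T' * 700}\n")
    manifest = write(tmp_path / "manifest.tsv", """\
        genome_id\tfasta_path\tcontig_ids\ttaxonomy\trole
        g1\ta.fasta\tc1\td__Bacteria;p__;c__;o__;f__;g__GenusA;s__GenusA sp1\tspike_in
        g2\ta.fasta\tc2\td__Bacteria;p__;c__;o__;f__;g__GenusA;s__GenusA sp2\tspike_in
        g3\tb.fasta\t*\td__Bacteria;p__;c__;o__;f__;g__GenusB;s__GenusB sp1\tsample_reference
        """)
    return manifest


def make_library(lengths, barcode="bc01", quality=20.0, **kwargs):
    reads = [
        ReadRecord(read_id=f"{barcode}_r{i}", length=length, mean_quality=quality,
                   barcode=barcode)
        for i, length in enumerate(lengths)
    ]
    return BarcodeLibrary(barcode=barcode, reads=reads, **kwargs)


@pytest.fixture
def uniform_library():
    return make_library([100] * 10)
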