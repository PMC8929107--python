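"""Characterize the transcript classes: length, GC, peak-expression
groups, and the lncRNA-vs-mRNA rank-sum comparisons."""

from pathlib import Path

import pandas as pd

from hypolnc import core_io
from hypolnc.lncrna_id import TranscriptRecord
from hypolnc.seq_features import (class_feature_table, compare_classes,
                                  peak_groups)
from hypolnc.synthetic import TruthTable

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    sim = BASE / "sim"
    records = [TranscriptRecord(i, s)
               for i, s in core_io.read_fasta(sim / "transcripts.fasta")]
    fpkm = core_io.read_expression(sim / "fpkm.tsv", sim / "meta.tsv")
    truth = TruthTable.from_tsv(sim / "truth.tsv")

    features = class_feature_table(records, truth.class_labels)
    features.to_csv(BASE / "transcript_features.tsv", sep="\t", index=False)

    _, peak_table = peak_groups(fpkm)
    peak_table.to_csv(BASE / "peak_groups.tsv", sep="\t", index=False)

    tests = pd.DataFrame([compare_classes(features, col)
                          for col in ("length_nt", "gc_content")])
    tests.to_csv(BASE / "class_comparisons.tsv", sep="\t", index=False)
    print(tests.to_string(index=False))
    print(peak_table.to_string(index=False))


if __name__ == "__main__":
    main()
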