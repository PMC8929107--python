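"""Call differential expression for the three oxygen contrasts in each
tissue and score recovery of the planted fold changes."""

from pathlib import Path

from hypolnc import core_io
from hypolnc.de_expression import call_de, nb_wald_test, results_table
from hypolnc.synthetic import TruthTable, contrast_key, parse_contrast_key

BASE = Path(__file__).resolve().parent.parent / "results"
CONTRASTS = [contrast_key(t, a, b)
             for t in ("heart", "liver")
             for a, b in ((6.5, 21.0), (10.5, 21.0), (6.5, 10.5))]


def main() -> None:
    sim = BASE / "sim"
    counts = core_io.read_expression(sim / "counts.tsv", sim / "meta.tsv")
    truth = TruthTable.from_tsv(sim / "truth.tsv")

    results = []
    for key in CONTRASTS:
        tissue, ox_a, ox_b = parse_contrast_key(key)
        results.extend(nb_wald_test(counts, ((tissue, ox_a), (tissue, ox_b))))
    parts, summary = call_de(results)
    results_table(results).to_csv(BASE / "de_results.tsv", sep="\t", index=False)
    summary.to_csv(BASE / "de_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))

    by_tid = {}
    for r in results:
        by_tid.setdefault(r.transcript_id, {})[
            contrast_key(r.contrast[0][0], r.contrast[0][1], r.contrast[1][1])] = r
    hits = total = 0
    for tid, planted in truth.planted_de.items():
        for key, lfc in planted.items():
            total += 1
            r = by_tid.get(tid, {}).get(key)
            if r and r.direction == ("up" if lfc > 0 else "down"):
                hits += 1
    print(f"planted fold-change recovery: {hits}/{total} "
          f"({100 * hits / total:.1f}%)")


if __name__ == "__main__":
    main()
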