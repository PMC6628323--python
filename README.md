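# cubkit

Codon usage bias analysis for in-frame coding sequences: composition
statistics, relative synonymous codon usage (RSCU), effective number of
codons (ENC) with ENC-plots, GC12-vs-GC3s neutrality regression, host
adaptation indices (CAI, RCDI, SiD), dinucleotide odds ratios and PCA over
59-dimensional RSCU vectors.

Four 59-codon RSCU reference tables ship with the package (two torque teno
sus virus genus profiles, `ttsuv1` and `ttsuv2`, and two swine host
profiles, `sus_scrofa` and `sus_scrofa_domestica`), and a synthetic CDS
generator provides ground-truth-bearing inputs for every statistic.

## Library overview

| Module | Contents |
| --- | --- |
| `cubkit.genetics` | genetic code / synonymous families, `CodingSequence` validation, FASTA I/O, codon counting |
| `cubkit.composition` | A/T/G/C%, silent-site A3s..C3s, GC1/GC2/GC12, GC3s |
| `cubkit.rscu` | RSCU profiles, representation thresholds (>=1.6 / <=0.6), preferred codons, ending census, virus-vs-host coincidence analysis |
| `cubkit.enc_neutrality` | Wright's ENC, expected-ENC curve, ENC-plot rows, GC12~GC3s regression with mutation/selection percentages |
| `cubkit.adaptation` | host references (RSCU TSV or codon-usage-database text), CAI, RCDI, SiD |
| `cubkit.dinucleotide` | sixteen odds ratios with 1.23 / 0.78 calls, linear or circular counting |
| `cubkit.multivariate` | covariance PCA over 59-codon RSCU vectors, deterministic axis signs |
| `cubkit.synthetic` | `GeneratorSpec`-driven CDS simulation (per-family codon weights, GC3 targets, Dirichlet bias), neutrality panels |
| `cubkit.report` | one-shot battery producing a TSV/JSON results bundle |

```python
from cubkit import load_fixture, sid, coincidence_analysis

virus, host = load_fixture("ttsuv1"), load_fixture("sus_scrofa")
print(sid(virus, host))                         # 0.093...
print(coincidence_analysis(virus, host).n_coincidence)  # 6 of 18 families
```

## CLI

```bash
cubkit validate genes.fasta                 # per-record CDS validation TSV
cubkit compose genes.fasta                  # composition table
cubkit rscu genes.fasta --host sus_scrofa   # RSCU + coincidence report
cubkit enc genes.fasta                      # ENC / GC3s / expected ENC
cubkit neutrality genes.fasta --group-by groups.tsv
cubkit adapt genes.fasta --host sus_scrofa --host sus_scrofa_domestica
cubkit sid --virus-profile v.tsv --host-profile h.tsv
cubkit dinuc genes.fasta [--circular]
cubkit pca genes.fasta --axes 2
cubkit simulate --spec spec.yaml --out sim.fasta --truth truth.json
cubkit report --fasta genes.fasta --out-dir out --host sus_scrofa
```

`--host` accepts a bundled fixture name, a 59-row `codon<TAB>rscu` TSV, or a
codon-usage-database style text file (`UUU 17.6(714298) ...`).

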