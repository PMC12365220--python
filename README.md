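# abcdiv — abundance-biased codon diversification

Constructs delivered by adeno-associated viral (AAV) vectors recombine
during production whenever they carry long repeated DNA stretches. FRET
sensors are the textbook case: their donor and acceptor fluorescent proteins
(CFP/YFP class) are both GFP descendants with >95 % nucleotide identity, so
packaged pools degenerate into mixtures of single fluorophores and the
sensor stops working in vivo. `abcdiv` implements **Abundance-Biased Codon
Diversification (ABCD)**: it redesigns a coding sequence with synonymous
codons so that it is maximally diverse — at the DNA level — from a reference
context and from itself, while

* never using a codon whose within-family usage fraction in the target
  organism falls below a chosen **bias** (protecting expression levels),
* excluding forbidden motifs (restriction sites, vector elements) on both
  strands, including across the reference junction, and
* preserving the encoded protein exactly.

Design quality is measured by an interaction-energy objective *f*: every
relative alignment register of `context ‖ sequence` is scanned for matched
runs (≥ 6 bp) that chain into duplex blocks when bridging the gap between
them is energetically favorable; `f = Σ_blocks exp(−E_block/rt)` with
nearest-neighbor ΔG°37 stacking energies, computed exactly in log10 space.
Fully diversified sequences land near `log10 f ≈ 4–6`; the conventional
safety threshold is `f < 10^7`; ≥95 %-identity FP pairs overflow double
precision (`log10 f > 308`). See `docs/methods.md` for the model.

The package also provides the audit tooling around the designer:
exact-repeat diagnostics (longest identical stretch, maximal-exact-match
histograms, dot plots), an NGS chimera analysis that quantifies the
recombined fraction and breakpoint profile of a sequenced pool from anchored
long reads, a matching read simulator, and seeded fixture generators
(FP-like homologous CDS pairs at any target identity).

## Worked example

Diversify a 239-residue protein against its own most-abundant-codon CDS
(the "self-diversification" workflow used to build drop-in replacements for
the YFP of an existing sensor), at a 10 % mouse abundance bias, excluding
the bundled restriction sites:

```python
from abcdiv import DiversificationTask, allowed_codons, back_translate, diversify
from abcdiv.fixtures import make_random_protein
from abcdiv.io import packaged_mouse_usage, packaged_restriction_sites

usage = packaged_mouse_usage()
protein = make_random_protein(239, seed=1, composition="fp")
reference = back_translate(protein, allowed_codons(usage, 1.0)).seq  # most-abundant CDS

result = diversify(DiversificationTask(
    target=protein,
    reference_context=reference,
    allowed=allowed_codons(usage, bias=0.10),
    forbidden=packaged_restriction_sites(),
    seed=11,
))
print(f"log10 f vs reference: {result.fscore_vs_reference.log10_f:.2f}")
print(f"longest identical stretch: {result.max_identical_bp} bp")
```

```
log10 f vs reference: 4.37
longest identical stretch: 7 bp
```

The redesigned CDS encodes the same protein but shares no stretch of 8 bp
or more with the reference (the original, fully identical encoding would
score `log10 f ≈ 483` — overflow), putting it far below the `10^7` safety
threshold. The same run from the shell:

```bash
abcdiv diversify --target protein.fasta --target-is-protein \
    --reference reference.fasta --bias 0.10 --seed 11 --out run1
```

writes `run1.fasta`, `run1.result.json` (scores, codon counts, seed) and a
reproducibility manifest. Other subcommands: `chain` (multi-FP sequential
diversification), `score`, `homology`, `chimera-simulate`,
`chimera-analyze`, `fixtures`.

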