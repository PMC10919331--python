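# pleoprophage

Detection and comparative analysis of integrated pleomorphic proviruses in
archaeal genomes.

Pleomorphic archaeal viruses (pleolipovirus-like) commonly integrate into
their host's chromosome via a tyrosine integrase. Integration duplicates a
short attachment (*att*) sequence, leaving the provirus flanked by two exact
direct repeats — *attL* and *attR* — with one copy typically overlapping a
tRNA gene and the other sitting next to the integrase gene. Excision reverses
this: a circular viral genome carrying a single reconstituted *att* copy
(*attV*). `pleoprophage` turns this biology into a tested pipeline for people
studying proviruses in archaeal (or bacterial) genome sequence:

- **Provirus finding** — all maximal exact direct-repeat pairs whose
  separation falls in a plausible element-size window (k-mer seeding with
  maximal extension, optional Hamming-mismatch tolerance), scored by
  tRNA-overlap and integrase-adjacency evidence.
- **Excision geometry** — reconstruction of the excised circular genome
  (`circle = genome[attR.start:attR.end] + genome[attL.end:attR.start]`,
  *attV* at position 0), with re-integration as its exact inverse, and
  in-silico PCR to predict the amplicon sizes that distinguish the integrated
  locus from the excised circle.
- **ORF annotation and synteny** — six-frame ORF calling under genetic code
  11 (origin-spanning ORFs on circular genomes included) and reciprocal-best
  homolog maps between genomes shaded by global amino-acid identity
  (BLOSUM62, affine gaps 11/1).
- **VP4 adaptation signatures** — N-glycosylation sequons (N-X-S/T, X ≠ P,
  overlapping occurrences counted), salt bridges (acidic O / basic N within
  4 Å), hydrophobic side-chain contact clusters, and a surface-charge summary
  with a CA-neighbor burial proxy; host-lineage groups compared with the
  unpaired pooled-variance *t*-test
  t = (x̄₁−x̄₂)/√(s_p²(1/n₁+1/n₂)), df = n₁+n₂−2.
- **Synthetic fixtures** — seeded generators for chromosomes with planted
  proviruses, protein sets with planted sequon counts, and toy structures
  with planted bridges/clusters, each returning machine-readable truth.

## Worked example

```python
from pleoprophage import FixtureSpec, call_proviruses, make_genome_with_provirus

genome, truth = make_genome_with_provirus(FixtureSpec(seed=1))
top = call_proviruses(genome)[0]
print(len(top.attL), top.circle_len, top.trna_overlap.label, top.score)
```

prints

```
27 17900 tRNA-Gly 127.0
```

— the planted element is recovered with its exact 27-nt *att* repeats; the
excised circle is 17,900 bp (the separation of the two repeat starts, i.e.
one *att* copy retained); the score is the repeat length plus 50 for the
tRNA overlap and 50 for the integrase within 2 kb. See `examples/` for
narrative scripts covering each capability (provirus finding, excision +
PCR geometry, ORF synteny, signature comparison), and
`pleoprophage --help` for the command-line interface
(`find`, `pcr`, `annotate`, `signatures`, `fixtures`, `convert`, `run`).

Real genomes are accepted as local FASTA/GenBank files (with tRNA and
integrase annotations from GenBank features or a GFF3); structures as
PDB/mmCIF.

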