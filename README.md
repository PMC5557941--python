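# barcogeo

Integrative species delimitation for DNA-barcoded specimens — built for
taxonomists working on groups (such as soil arthropods like springtails)
where diagnostic morphology is scarce and single-method delimitation is
unreliable. The package combines four lines of evidence on one set of
barcoded individuals:

1. **Molecular** — barcode-gap partitioning of K2P pairwise distances over a
   scan of prior intraspecific divergences (ABGD-style), with recursive
   within-group splitting and widest-plateau selection;
2. **Geographic** — single-linkage clustering of populations (sites within a
   5 km radius) inside each morphospecies, across a dispersal-threshold scan
   (10–500 km);
3. **Phylogenetic** — neighbour-joining trees with column-bootstrap support,
   and monophyly assessment of candidate species on built or imported
   (newick) trees;
4. **Morphological** — stability and pairwise diagnosability of discrete
   characters (e.g. pseudocelli formulae), excluding deformed specimens.

A lineage recognized by all criteria is a *validated species*; one that is
monophyletic and molecularly/geographically congruent but morphologically
indistinguishable from another lineage is a *cryptic species*; anything else
is *unresolved*. A seeded simulator generates datasets with planted species
truth (divergence bands, ranges, lumped morphospecies, cryptic pairs,
deformities) so every step can be checked against a known answer.

## The statistics in brief

For each sequence pair, over the sites where both have an unambiguous base
(pairwise deletion of gaps and N), with transition proportion *p* (A↔G, C↔T)
and transversion proportion *q*:

    d = -1/2 ln(1 - 2p - q) - 1/4 ln(1 - 2q)        (Kimura 1980)

Given a prior intraspecific divergence *P*, sort all pairwise distances,
skip ranks ≤ *P*, and find the rank gap `g_i = d_(i+1) − d_(i)` that is
largest among those exceeding `X · r_i`, where `r_i` is the mean of up to
*w* preceding gaps (defaults X = 1, w = 10). The midpoint of that gap is the
clustering threshold; groups are connected components of the *d* ≤ *t*
graph. Scanning *P* over a log grid from 0.001 to 0.14 (20 priors) and
taking the widest plateau of the primary group count gives the molecular
partition. Geographic distances are great-circle km (R = 6371.0088 km).

## Worked example

`examples/04_integrative_validation.py` runs the full pipeline on the
study-shaped preset (22 planted species, 144 specimens, 10 morphospecies,
4 cryptic pairs, 1 widespread species):

```
$ python examples/04_integrative_validation.py
molecular partition: k=22, ARI vs truth 1.00
distance summary: intra 0.0202 (0.0061-0.0328) [402 pairs], inter 0.1654 (0.0943-0.2476) [9894 pairs]
geographic k by threshold: {'10km': 23, '20km': 23, '50km': 23, '100km': 23, '200km': 23, '300km': 22, '400km': 22, '500km': 21}
validation: {'validated_species': 13, 'cryptic_species': 8, 'unresolved': 1}
incongruent with geography: ['G22']
```

Reading the output: the gap scan recovers all 22 planted species exactly
(adjusted Rand 1.0 against the truth), with pooled within-species K2P
divergence ≈ 2% and between-species ≈ 17%. Geography at 50 km yields 23
putative species — one more than the molecular count because the single
widespread species occupies two ranges over 150 km apart, so its molecular
cluster (`G22`) is flagged incongruent and left unresolved. The 8 cryptic
verdicts are exactly the members of the 4 planted cryptic pairs: distinct
lineages on sequence and geography, identical on every character. The
remaining 13 species pass all three criteria.

The other examples demonstrate one capability each: the prior scan and
histogram (`01`), the geographic threshold rule and its single-linkage
chaining (`02`), NJ/bootstrap/monophyly (`03`). A CLI mirrors the library
(`barcogeo simulate | validate-inputs | distances | gapscan | geodelim |
njtree | congruence | validate`).

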