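# dietniche

Quantitative dietary ecology for stomach-flushed predators: composition
tables, trophic niche breadth and overlap, and permutation-based community
comparison, built around a three-species syntopic frog assemblage
(*Microhyla heymonsi*, *M. mukhlesuri*, *Occidozyga lingnanica*).

It is written for herpetologists and trophic ecologists who have long-format
stomach-content data (one row per prey item, with predator morphometrics)
and want the standard analysis chain without stitching together spreadsheet
formulas and R snippets:

- prey volume as a prolate spheroid, V = 4π/3 · (L/2) · (W/2)²;
- per-category frequency of occurrence, numeric and volumetric proportions,
  and the index of relative importance IRI = (%F + %N + %V)/3;
- Simpson heterogeneity 1−D (finite-sample), Shannon H′ and evenness
  J′ = H′/ln S;
- Levins standardised niche breadth B_sta = (B−1)/(n−1), B = 1/Σp²;
- Pianka pairwise niche overlap O_jk = ΣP_ij P_ik / √(ΣP_ij² ΣP_ik²);
- Bray–Curtis dissimilarity between stomachs, Clarke's ANOSIM permutation
  test, and non-metric multidimensional scaling (Kruskal stress-1);
- Pearson and Kendall tau-b correlations for morphometrics vs diet volume;
- a seeded synthetic-data generator reproducing the study's published
  summary structure (category multinomials, over-dispersed per-stomach
  counts, log-normal prey sizes, copula-correlated morphometrics), so the
  whole pipeline is testable without raw field data.

See `docs/methods.md` for the statistical conventions and their rationale.

## Worked example

```python
import dietniche as dn

ds = dn.generate(dn.default_study_config(seed=42))   # 116 stomachs, 1697 items

tab = dn.category_table(ds, "Microhyla heymonsi")
print(tab.to_dataframe(digits=2).head(3))

profs = [dn.NicheProfile.from_dataset(ds, sp) for sp in sorted(ds.species_set)]
for p in profs:
    print(p.species, dn.diversity(p).one_minus_D, dn.levins(p).B_sta)
print(dn.overlap_matrix(profs).O.round(2))

m = dn.build_matrix(ds, "abundance")
d = dn.bray_curtis(m)
print(dn.anosim(d, m.species_labels, n_permutations=999, seed=42))
print(dn.nmds(d, dims=2, seed=42).stress)
```

prints (abridged):

```
            label  f_count  n_count  pct_f  pct_n  pct_v   iri
       Termitidae       26      389  55.32  93.51  93.40 80.74
       Formicidae       12       18  25.53   4.33   4.44 11.43
Larvae Coleoptera        3        3   6.38   0.72   0.94  2.68
Microhyla heymonsi     1-D=0.12  B_sta=0.04
Microhyla mukhlesuri   1-D=0.39  B_sta=0.08
Occidozyga lingnanica  1-D=0.90  B_sta=0.37
[[1.   0.97 0.47]
 [0.97 1.   0.5 ]
 [0.47 0.5  1.  ]]
ANOSIM r=0.4592 p=0.001  (999 permutations, seed 42)
NMDS stress=0.171
```

Read it as: the synthetic *M. heymonsi* diet is termite-dominated
(IRI ≈ 81% for Termitidae), hence a narrow niche (B_sta 0.04, 1−D 0.12),
while *O. lingnanica* is a generalist (B_sta 0.37, 1−D 0.90); the two
*Microhyla* overlap almost completely (O ≈ 0.97) but each overlaps the
floating frog only moderately (≈ 0.5); ANOSIM finds the three diets
significantly distinct overall (r = 0.46, p = 0.001), and the 2-D NMDS
stress 0.171 is below the conventional 0.2 adequacy threshold.

The same pipeline runs from the shell:

```sh
dietniche simulate --study-defaults --seed 42 --out diet.csv
dietniche validate  --input diet.csv
dietniche summarize --input diet.csv --outdir out/
dietniche compare   --input diet.csv --outdir out/ --permutations 999 --seed 42
```

Every output carries a provenance header (version, seed, config hash) and
deterministic commands are byte-identical across re-runs.

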