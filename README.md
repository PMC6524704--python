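# pepkin

**Physicochemical barcoding and spectral-count kinetics of complex
peptidomes.**

`pepkin` is for peptidomics practitioners who monitor a complex peptide
mixture over time by LC-MS/MS — typically a protein-hydrolysate culture
medium such as yeast extract during a bacterial fermentation — and want to
know *which kinds of peptides* are consumed, released or untouched.
Individual non-tryptic peptides are usually identified from a single
fragmentation spectrum, which is far too sparse for peptide-level
time-course statistics. `pepkin` therefore pools peptides into
physicochemical **classes** and performs the kinetics at the class level.

## Method

Each peptide sequence is described by nine composition-based descriptors:

| # | descriptor | definition |
|---|------------|------------|
| 1 | length | residue count |
| 2 | GRAVY | mean Kyte–Doolittle hydropathy |
| 3 | bulkiness | mean Zimmerman side-chain cross-section (Å²) |
| 4 | polarity | mean Grantham polarity |
| 5 | net charge | Henderson–Hasselbalch charge at pH 6.0 (termini included) |
| 6 | basic fraction | (K + R + H) / length |
| 7 | acidic fraction | (D + E) / length |
| 8 | aromatic fraction | (F + W + Y) / length |
| 9 | proline fraction | P / length |

The range of each descriptor is split into three intervals
(e.g. length ≤ 9 / [10; 12] / ≥ 13; net charge < 0 / [0; 1] / > 1;
residue fractions = 0 / ]0; 0.12] / > 0.12), and the peptide's class — its
9-digit **barcode** — is the concatenation of its interval digits, giving
3⁹ = 19,683 possible classes.

Class-level spectral counts per sample (replicate × timepoint) form a
contingency table. Classes below 5 spectra in every sample are discarded;
classes varying by less than 50% between their minimal and maximal
per-timepoint mean abundance are set aside as *constant*. For each
remaining class, counts y are modelled as Poisson with one rate per
timepoint, and the time effect is a likelihood-ratio (deviance) test
against a single grand rate,

    LRT = 2 Σᵢ yᵢ log(μ̂_time(i) / μ̂_null)  ~  χ²(T − 1) under H₀,

with Benjamini–Hochberg FDR across classes and a call at adjusted
p ≤ 0.01. Significant classes are labelled *decreasing*, *increasing* or
*fluctuating* from the Spearman correlation of counts against time plus
an endpoint comparison; constant classes are reintegrated, and the four
kinetic profiles are characterized by rank tests on peptide property
distributions and a PCA of the standardized descriptor space.

A synthetic-data module generates full peptidome time courses with known
planted profiles, so the whole pipeline can be validated end to end
without raw MS data.

## Worked example

```python
>>> import pepkin
>>> pv = pepkin.compute_property_vector("KGSIDEQHPRYGG")
>>> {k: round(v, 3) for k, v in pv.as_dict().items()}
{'length': 13, 'gravy': -1.731, 'bulkiness': 12.301, 'polarity': 9.508,
 'net_charge': 0.781, 'frac_basic': 0.231, 'frac_acidic': 0.154,
 'frac_aromatic': 0.077, 'frac_proline': 0.077}
>>> pepkin.assign_barcode(pv)
'321223322'
```

The peptide is 13 residues long (length interval 3), has GRAVY −1.73
(interval 2), and so on through the nine digits.

A complete synthetic run (generation, barcoding, filtering, testing,
profiling):

```python
>>> psm, truth = pepkin.generate_dataset(seed=42)
>>> result = pepkin.run_all(psm)
>>> result.manifest["n_classes"], result.manifest["n_significant"]
(1256, 35)
>>> result.profile_summary
             n_classes  n_peptides  n_spectra
profile
decreasing          12         209       2226
increasing          12          90       3418
constant            10          71       1030
fluctuating         11         342       2344
```

Here 1,256 barcode classes were observed; 35 passed both filters and
varied significantly over time (adjusted p ≤ 0.01), and together with the
reintegrated constant classes they partition into the four kinetic
profiles shown, with their member-peptide and spectra totals.

The same pipeline is available from the shell:

```sh
pepkin simulate --seed 42 --out psm.tsv
pepkin run-all --in psm.tsv --out-dir results/
```

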