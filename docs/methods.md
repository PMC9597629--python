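# Methods

## The mirror-protease validation model

A peptide identified from a six-frame translation database carries far
less prior support than one from an annotated proteome, so novel-peptide
calls need evidence beyond a search-engine score. `mirrorpg` builds that
evidence from four orthogonal sources:

1. **Mirror peptide pairs.** Trypsin cleaves after K/R, lysargiNase
   before K/R. An interior sequence S flanked by K/R therefore appears as
   the tryptic peptide `S+r` and the lysargiNase peptide `r'+S`. The two
   spectra are complementary: trypsin's C-terminal K/R favours y ions,
   lysargiNase's N-terminal K/R favours b ions. A pair is accepted when
   the trimmed cores are the same string *at the same genomic locus*
   (exact equality, no I/L collapsing — the locus already disambiguates).
   Both members' matched ions are projected onto the pair's
   *super-sequence* (lysargiNase K/R prefix + core + tryptic K/R suffix):
   a member b_i lands on super bond `offset + i`, a member y_j on
   `offset + (n_member − j)`. Merged coverage uses the super-sequence
   bond count as denominator; by construction it dominates each member's
   own coverage.
2. **Target-decoy q-values.** Decoys are whole-entry reversals of the
   six-frame database, digested identically. PSMs are ranked by score
   with decoys above targets at ties (conservative); FDR at a rank is
   `#decoys / max(1, #targets)` at or above it, and the q-value is the
   running minimum of FDR from the bottom of the ranking. Downstream
   evidence requires q < 0.01. With no decoy PSMs in a run all q-values
   are 0 and a warning is logged.
3. **¹⁴N/¹⁵N spectrum similarity.** Metabolic ¹⁵N labeling yields a heavy
   twin of every peptide, shifted by 0.9970349 Da per nitrogen atom but
   otherwise fragmenting identically. The ¹⁴N and ¹⁵N PSMs of a peptide
   are compared by the cosine of their annotated fragment-intensity
   vectors over the union of (series, index, charge) keys; validation
   requires cosine > 0.9.
4. **Continuous b/y pairs.** A backbone bond with both b_i and y_{n−i}
   matched is a directly double-confirmed cleavage position; events must
   show ≥ 3 such pairs on at least one supporting peptide (merged
   metrics count for mirror members). Both the pair count and the longest
   consecutive run are computed; the filter uses the count.

## Pipeline

`run_pipeline` executes: six-frame database (stop-to-stop, min 7
residues) → per-protease digestion (≤ 2 missed cleavages, 7–45 residues,
peptides containing X excluded) → per-run search (precursor and fragment
tolerance 20 ppm, fixed carbamidomethyl-C, 1+ b/y ions, rank-1 PSM per
spectrum, q < 0.01) → mirror pairing and evidence aggregation →
classification → targeted N-terminome search → start inference → event
filters → TSV/GFF3 reports. The run is fully deterministic given the
configuration and inputs.

**Classification.** A peptide wholly inside an annotated CDS, in frame, is
"annotated". A peptide in the same stop-to-stop ORF as a CDS that shares
its bounding stop, but starting upstream of the annotated start codon,
contributes to that gene's `n_term_extension` event (a peptide merely
covering the start must cross it by at least one codon, which in-frame
coordinates make automatic). A peptide in an ORF with no in-frame CDS
overlap contributes to a `novel_orf` event keyed by the ORF.

**Start-codon inference.** Given a dimethyl-labelled N-terminal peptide
starting at ORF residue p: if residue p is a small residue
({A,S,T,G,P,V,C}, the aminopeptidase specificity) and the codon at p−1 is
a canonical start (ATG/GTG/TTG/CTG), the start is p−1 with the initiator
removed; otherwise if the codon at p is canonical the start is p with the
initiator retained; otherwise, under direct dimethyl evidence, the codon
at p−1 is accepted even when non-canonical (covering observed GTC starts)
and flagged. The aminopeptidase branch is evaluated *before* the codon-at-p
branch: when an initiator was removed, the observed first residue may
itself be encoded by a canonical-looking codon (a penultimate V encoded
GTG), and testing p first would mistake it for the start. Without
N-terminome evidence the nearest in-frame canonical start at or upstream
of the most upstream supporting peptide is proposed with `low`
confidence; the same removal shortcut applies first. The inferred
position is never downstream of any supporting peptide. The residue set
and codon sets are shared constants with the simulator, so inference is
exactly recoverable on simulated data.

**Targeted N-terminome search.** The dimethyl N-terminome run is searched
semi-specifically (≤ 3 missed cleavages, dimethyl fixed at K and at the
peptide N-terminus) against the ORFs that already carry candidate events,
rather than the whole database. Mature protein N-termini are not tryptic
boundaries, so the semi-specific mode is what makes them findable; the
targeted scope keeps the combinatorially larger semi digest proportionate
to its role of pinning start sites for a handful of loci.

## Mass and fragment model

Monoisotopic residue masses at full elemental precision; water
18.0105647 Da, proton 1.0072765 Da. b_i = sum of the first i residue (+
modification) masses + z protons over z; y_j adds water. Modification
deltas are Unimod standard values (carbamidomethyl +57.021464, oxidation
+15.994915, acetyl +42.010565, dimethyl +28.031300, pyroGlu −18.010565
from E / −17.026549 from Q). ¹⁵N mode models *full* labeling: every
nitrogen, including those added or removed by modifications
(carbamidomethyl +1 N, pyroGlu-Q −1 N), shifts by 0.9970349 Da. Fragment
charges: 1+ (2+ available via configuration). a/c/z ions, neutral losses
and isotope envelopes are not modelled — only b/y coverage is quantified.
The raw PSM score is a documented surrogate — matched-fragment count plus
the explained fraction of total peak intensity — deterministic and
monotone in evidence, but its absolute values are not comparable with any
commercial engine's score.

## The synthetic study

The generator emulates the experimental design: one genome, two parallel
digests, equal-mixed ¹⁴N/¹⁵N cultures, a dimethyl N-terminome subset.
Defaults (the study conditions): 60 kb chromosome, 60 genes of 60–180
codons on both strands, 4 genes with the annotated start shifted 3–10
codons downstream of the true start, 3 ORFs omitted from the annotation;
peptide detection probability 0.9; fragment dropout 0.15; 10 uniform
noise peaks per spectrum; log-normal fragment intensities (μ = 0,
σ = 0.5); every detected peptide also emitted as a ¹⁵N spectrum with the
*same* dropout pattern and intensities (metabolic-label twins are nearly
identical in practice); half of the planted events receive a dimethyl
N-terminal spectrum; precursor charge fixed at 2 (inside the accepted 2–6
range). Seed 17 is the default.

Constructional guarantees, chosen so that the planted truth is
unambiguous and in-principle detectable (not so that any particular test
passes):

- Intergenic spacers carry an all-frame stop cassette every ~45 nt, so
  every gene owns its stop-to-stop ORF and hidden ORFs cannot merge with
  neighbours.
- Mis-annotated genes carry a K/R at residue 2 and a second K/R at codon
  10–40, so fully specific peptides of searchable length (7–45 residues)
  exist upstream of the annotated start; without such sites the planted
  event would be invisible to any specific search and the simulation
  would test nothing. The extension window contains no in-frame canonical
  start codon other than the true one, making the upstream scan
  well-posed.
- Initiator removal follows the same shared residue set as inference.

What the simulator does **not** model — and hence what passing tests do
not show about real data: charge-state and retention-time variation,
isotope envelopes, co-eluting chimeric spectra, semi-tryptic background
in the main runs, partial ¹⁵N enrichment, intensity correlation between
label twins below 1.0, the protease-specific b/y intensity asymmetry
(real tryptic spectra favour y ions and lysargiNase spectra b ions, which
is what makes merged coverage gains dramatic in practice; the simulator
drops b and y symmetrically), and homology between loci (each planted gene is a
distinct random sequence, so peptide-to-locus mapping is nearly always
unique). FDR calibration realism is also limited: with clean spectra the
decoy competition is weak and most q-values are 0.

## Numerical and edge-case choices

- Peak matching is boundary-inclusive at 20 ppm with a 1e-12 relative
  slack so the inclusive boundary survives floating-point rounding; each
  fragment takes its closest peak, and one peak may serve several
  fragments.
- Duplicate peak m/z values are merged (intensities summed) on spectrum
  construction, making peak lists strictly ascending.
- Codons containing ambiguity codes translate to X; X never splits an
  ORF, and peptides containing X are never generated.
- The genome is treated as linear (no origin-spanning ORFs): terminal
  stop-less segments of each frame are kept as entries.
- Alternative starts GTG/TTG/CTG translate as their standard residues
  (V/L/L) inside ORFs; start assignment happens only at reannotation, and
  the simulated initiator follows the same convention.
- Ties in PSM candidate selection break decoy-first, then
  lexicographically; q-value ties are therefore permutation-invariant.
- Event uniqueness counts distinct peptide sequences; the "two protease
  products" alternative to a mirror pair requires products of *both*
  proteases (counting any two distinct sequences would duplicate the
  unique-peptide filter).
- Problem sizes in the test suite (genome lengths 12–60 kb, 8–60 genes,
  up to ~6,000 simulated spectra) were chosen to exercise every code path
  at interactive runtimes; all thresholds are the defaults above.

## Known limitations

- Variable modifications are represented (specs, masses, nitrogen deltas)
  but candidate enumeration in the search applies fixed modifications
  only, plus the forced N-terminal dimethyl of the N-terminome mode.
- No protein-level inference or grouping; evidence is peptide-level.
- No homology screening, phylogenetics, or RNA-seq/Ribo-seq integration;
  those validations are outside this package's scope.
- The surrogate raw score is not calibrated across runs; only its within-
  run ranking matters (q-values are computed per run).
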