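# clonediv

Quantification of immunoglobulin **intraclonal diversification (ID)** from
IGHV repertoire sequencing, without unique molecular identifiers.

In chronic lymphocytic leukemia (CLL) and other B-cell malignancies, the
expanded pathological clone can keep acquiring somatic hypermutations in its
rearranged IGHV gene after transformation, producing a spectrum of subclones.
The degree of this diversification is biologically meaningful — it carries the
signature of ongoing AID activity — and prognostically relevant within
IGHV-mutated disease.  Measuring it from deep amplicon sequencing is
confounded by PCR/sequencing artifacts, which this package detects and
corrects before any diversity statistic is computed.

`clonediv` is aimed at computational immunologists and hematology researchers
working with AIRR-seq style data (AIRR Rearrangement TSV, FASTA/FASTQ).

## The measurement

1. **Pathological clone** — reads are grouped by IGHV/IGHJ gene and CDR3
   (exact junction match by default); the most abundant group is the clone.
   A *subclone* is any retained clone sequence differing from the major
   sequence by ≥ 1 nucleotide.
2. **Gates** — sequences below 0.1% of the clone's reads are discarded and
   frequencies renormalized; samples with < 5000 clone reads are
   non-evaluable (so a 0.1% subclone always has ≥ 5 supporting reads).
3. **Systematic-error correction** — recurrent artifacts are identified
   across a cohort as (5-mer context, alternative base) pairs that appear in
   ≥ 5 distinct clones as low-frequency (< 2%) variants with mean Phred < 20,
   and reverted to the major-subclone base before the gates are applied.
4. **Diversity** — for subclone frequencies *p* the Hill number of order *q*
   is ^q*D* = (Σᵢ pᵢ^q)^{1/(1−q)}, with the Shannon limit at *q* = 1.  The
   working statistic is the **inverse Simpson index**, iSI = ^2*D* = 1/Σᵢ pᵢ²,
   the effective number of equally abundant subclones.  Samples are called
   **ID_high** (iSI ≥ 1.2) or **ID_low** (iSI < 1.2).
5. **Signatures and trees** — each mutation is classified against AID
   hotspots WRC/GYW and coldspots SYC/GRS (W=A/T, R=A/G, Y=C/T, S=G/C, on
   germline context, both strands), replacement/silent under the standard
   genetic code, FR/CDR region, and sharing across subclones; subclones are
   arranged in a germline-rooted minimum-spanning lineage tree.
6. **Survival** — Kaplan–Meier and log-rank machinery plus a maximally
   selected log-rank cutpoint search (the procedure that motivates the 1.2
   iSI threshold), with a Miller–Siegmund multiplicity adjustment.

A UMI-based path (pattern extraction, Hamming-1 collapse, per-position
majority consensus) is included to cross-validate the UMI-free measurement.
Because no public dataset accompanies the method, the package ships a
first-class simulator that generates repertoires with known subclone
composition, AID-hotspot-biased mutations, random and context-systematic
sequencing errors, and survival cohorts with group-dependent hazards.

## Worked example

Simulate five repertoires (~15,000 reads each) and run the full pipeline:

```sh
$ clonediv simulate --seed 7 --n-samples 5 --out demo
wrote 5 samples to demo
$ clonediv run --input demo --out demo/out
5 evaluable samples, 0 excluded, ID_high fraction 0.600
$ cat demo/out_summary.tsv
sample_id  clone_reads  n_subclones  p_major   isi       id_class  mutational_status  tree_nodes  tree_depth  tree_branch_length
S000       15000        5            0.373901  3.591370  ID_high   M                  6           2           21
S001       15000        4            0.376012  3.575622  ID_high   M                  5           2           21
S002       15000        3            0.954289  1.095753  ID_low    M                  4           2           17
S003       15000        5            0.545577  2.627189  ID_high   M                  6           2           22
S004       15000        1            1.000000  1.000000  ID_low    M                  2           1           15
```

Reading the rows: `S004` collapsed to a single sequence (iSI = 1, no
diversification), `S002` has a dominant major subclone (p_major 0.95, iSI
1.10, ID_low), while `S000` spreads its reads over five subclones (iSI 3.59,
ID_high) and correspondingly grows a larger lineage tree.  The simulator's
`demo/truth.json` records the planted frequencies; the recovered iSI values
sit within multinomial sampling error of the planted ones (e.g. S000: 3.59
recovered vs 3.65 planted), after the cohort-learned artifact blacklist
(`demo/out_blacklist.tsv`) has been applied.

Library use mirrors the CLI:

```python
import clonediv as cd

reads, truth = cd.simulate_repertoire(cd.SimulationConfig(), seed=1)
clone = cd.identify_pathological_clone(reads)
profile = cd.enumerate_subclones(clone[1], total_sample_reads=15_000)
print(cd.diversity_profile(profile).isi)
```

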