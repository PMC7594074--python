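# Methods

## The assessment model

`fairmi` treats a FAIRness assessment as a pure function from an *evidence
bundle* to a row of 15 indicator scores. A bundle collects everything the
rubric consults for one use case:

* **DatasetQuery** — the keywords a researcher used to find the dataset and
  the accession of the dataset they chose. The keywords are part of the
  rubric on purpose: F2 asks whether the metadata would have led this
  researcher to this dataset, so FAIRness here is relative to a use case,
  not absolute.
* **DatasetMetadata** — the repository's metadata document, reduced to a
  canonical record (identifiers, flattened attributes, cross-references,
  publication provenance, raw text).
* **RegistryRecord** — the repository-level entry from a registry of
  repositories (persistent-identifier badge, availability policy, license).
  Repository-level facts are read from the registry rather than scraped
  from free text because the registry is the one place they are exposed in
  a machine-readable, uniformly named way.
* **RetrievalResult** — one HTTP GET outcome (scheme + status).
* a manual **searchable-resource flag** for F4.

Scoring is deterministic and side-effect free; identical bundles give
identical rows. Evidence that cannot be obtained (missing registry record,
absent manual flag, replay miss) raises an error instead of scoring 0 —
"failed the criterion" and "could not determine" are different facts and
are never conflated.

### Score semantics

All indicators are binary except F2 (matched keywords / total keywords) and
R1.2 (1 / 0.5 / 0 for all / some / none of {authors, email, title}).
Three distinct "no value" states survive serialization and plotting:
score 0 (checked, failed), *not assessed* (I2 and R1.3 — drawn as crosses),
and *missing* (a qualitative cell judged "unclear" — drawn as nothing).
No composite FAIR score is computed anywhere; aggregate rankings invite
misuse and hide exactly the per-indicator detail the balloon plot exists to
show.

### Retrieval-mode tags

Each indicator carries a canonical retrieval mode — automatic (API-driven:
F2, F3, A1 family, A2, R1, R1.1, R1.2) or manual (F1, F4, I1, I3) — that
the balloon plot encodes as circle vs diamond. The tags describe how the
reference assessment procedure obtained its evidence. This implementation
automates some of the manually tagged checks (F1 from the parsed registry
record, I1 from a well-formedness test), but keeps the canonical tags as
the default so rendered plots keep their shapes; every scorer accepts a
`mode=` argument to re-tag.

## Interpretation choices

The rubric's published wording leaves several operational details open;
these are the package's choices:

* **F2 matching** — case-insensitive substring containment of each whole
  keyword phrase against the serialized metadata text (all fields, not a
  selected subset). No tokenization or stemming: multi-word keywords match
  as phrases. Containment is the weakest assumption that makes "all
  keywords were found" well defined.
* **"Protocol is HTTP"** — HTTPS counts as HTTP-family; the rationale for
  A1.1/A1.2 (open, free, universally implementable, supports
  authentication) applies equally and real endpoints redirect to HTTPS.
* **"Filled" fields** — present *and* nonblank after whitespace trimming; a
  present-but-empty tag carries no information.
* **F3** — trimmed, case-insensitive exact equality between the query
  accession and a metadata identifier. Accessions are exact tokens; fuzzy
  matching would manufacture findability.
* **I3 "other" metadata** — cross-references whose target differs from all
  of the dataset's own identifiers. Same-host dataset-to-dataset links
  count; a reference to itself does not.
* **F4** — no search-engine scraping (volatile, ToS-hostile). The evidence
  is a manual override or a pluggable checker; the packaged values reflect
  a snapshot, not current reality.
* **Registry field names** — the registry's "doi icon" is mapped to a
  persistent-identifier element (`pidSystem`, true for DOI/Handle/ARK/PURL/
  URN tokens, false for "none"); the availability policy and license
  name/URL elements default to `dataAvailabilityPolicy`,
  `dataLicenseName`, `dataLicenseURL`. All element names are configuration
  (`RegistryFieldConfig`) because registries rename fields.
* **Unknown dialects** are a configuration error rather than a silent
  generic fallback; callers who want flattening say `dialect="generic"`
  explicitly. A typo that silently degrades provenance extraction would
  corrupt R1.2 without a trace.

## Metadata dialects

Dialect field maps are data, not code (`data/dialects.yaml`): each dialect
names its document format, identifier path, cross-reference path/keys and
provenance attribute paths. The same map drives parsing and serialization,
so `parse(serialize(m))` round-trips every field the dialect can express —
a dialect without provenance attributes (GEO, eNanoMapper, caNanoLab,
NanoCommons) cannot carry provenance, which is precisely why those
use cases score R1.2 = 0. ArrayExpress exposes authors+email+title (3/3),
ChEMBL authors+title (2/3). The emulated document shapes are synthetic
simplifications of each repository's API output, not captures of it.

## The synthetic-evidence generator

A `FixtureProfile` states the intended FAIRness of a use case
(keyword coverage, DOI badge, policy, license, provenance subset,
cross-reference, search-resource presence, attribute surplus), and
`generate_evidence` builds a bundle that must score exactly as the profile
dictates — this self-consistency contract is validated at generation time
and property-tested over randomized profiles. Filler text is drawn from a
fixed vocabulary of nonsense tokens disjoint from any plausible keyword or
accession, so filler can never fake a keyword match; a profile whose
excluded keywords collide with the generated document (e.g. one keyword
contained in another) is rejected as unsatisfiable rather than silently
mis-scored.

The six builtin profiles encode the six evaluated use cases — a Parkinson's
disease expression study (ArrayExpress), a WDR45 mutation study (GEO) and a
TiO2 nanoparticle toxicity question asked of eNanoMapper, caNanoLab, ChEMBL
and NanoCommons — with their reference score pattern; the keyword lists
paraphrase the research questions and are stand-ins, not the researchers'
literal queries. What passing the self-consistency suite shows is that the
scoring engine and the generator agree on the rubric under controlled
conditions; it does not show that live repository APIs still expose the
fields assumed here, that real metadata are as clean as the synthetic
documents, or that the snapshot-dependent facts (registry content, search
indexing) still hold.

## The balloon plot

One mark per assessed cell: size is an affine, strictly increasing function
of the score (area 30 pt² at 0 — zero scores stay visible — to 330 pt² at
1), shape encodes the retrieval mode, color the FAIR category (defaults:
Findable `#1f77b4`, Accessible `#d62728`, Interoperable `#2ca02c`,
Reusable `#ff7f0e`; all style values are a YAML config away). SVG output
embeds no timestamps and uses a fixed hash salt, so identical inputs give
byte-identical files.

## Numerical and degenerate-input notes

* F2 values are exact binary fractions whenever the keyword count is a
  power of two and otherwise the closest double; equality tests compare
  against `m/n` computed the same way.
* A profile's `keyword_coverage` must be expressible as m/n for its n
  keywords (checked to 1e-9) or the profile is rejected.
* An empty keyword list is rejected at query construction (the F2 ratio is
  undefined), an empty metadata document at parse time, an empty matrix at
  build time, and an empty mark list at render time.
* Replayed and live retrievals produce identical `RetrievalResult`s given
  identical facts; a recorded connection failure has an absent status and
  scores A1 = 0 while the URL scheme still scores A1.1/A1.2.

## Problem sizes

The bundled study is deliberately desk-scale: six use cases × 15
indicators, documents of a few kilobytes, and the property suites run 110+
randomized profiles and 40 randomized keyword sets — enough to exercise
every branch of the rubric while the whole test suite stays in the
seconds range.

## Known limitations

Live mode (`--live`, registry URL templates) is plumbing that exists but is
exercised only against unreachable-host error paths in the suite; the
workflow's claims are about the rubric, not about today's API responses.
Metadata standards emission (Dublin Core, DataCite, schema.org) and
FAIRness of vocabularies (I2) are out of scope.
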