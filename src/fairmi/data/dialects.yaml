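# Declarative field maps for repository metadata dialects.
#
# Repositories expose no shared metadata schema, so each dialect names where
# the canonical fields live in its documents: dotted paths are element/key
# paths below the document root (the XML root tag itself is not part of the
# path). The document shapes emulated here are SYNTHETIC: plausible
# simplifications of each repository's API output, not captures of it.
#
# Keys per dialect:
#   format            xml | json | any
#   root              XML root tag (used when serializing; ignored for json)
#   identifier_paths  paths whose leaf values are dataset accessions
#   xref              path to cross-reference entries + the entry keys that
#                     hold the target dataset id and host
#   provenance        paths of the publication provenance attributes this
#                     dialect exposes; omit a field the repository lacks
#
# A dialect with an empty provenance map exposes no provenance attributes at
# all, whatever the document contains.

arrayexpress:
  format: xml
  root: experiments
  identifier_paths: [experiment.accession]
  xref:
    path: experiment.crossreferences.crossref
    id_key: accession
    host_key: host
  provenance:
    authors: experiment.bibliography.authors
    email: experiment.bibliography.email
    title: experiment.bibliography.title

geo:
  format: xml
  root: MINiML
  identifier_paths: [Series.Accession]
  xref:
    path: Series.Relations.Relation
    id_key: Target
    host_key: Host
  provenance: {}

enanomapper:
  format: json
  identifier_paths: [dataset.id]
  xref:
    path: dataset.seeAlso
    id_key: id
    host_key: host
  provenance: {}

cananolab:
  format: json
  identifier_paths: [sample.id]
  xref:
    path: sample.associatedSamples
    id_key: id
    host_key: host
  provenance: {}

chembl:
  format: json
  identifier_paths: [document.document_chembl_id]
  xref:
    path: document.cross_references
    id_key: xref_id
    host_key: xref_src
  provenance:
    authors: document.authors
    title: document.title

nanocommons:
  format: xml
  root: nanocommons
  identifier_paths: [dataset.identifier]
  xref:
    path: dataset.links.link
    id_key: target
    host_key: host
  provenance: {}

generic:
  format: any
  root: dataset
  identifier_paths: [identifiers]
  xref:
    path: crossReferences
    id_key: id
    host_key: host
  provenance: {}
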