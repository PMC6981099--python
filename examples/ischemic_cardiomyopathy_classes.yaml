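# Example functional-class curation for an ischemic-heart-disease study.
#
# The enrichment engine is class-agnostic: a class map simply names the
# disease-relevant functional classes and lists the GO BP term ids that
# belong to each.  This file shows the six classes such a study would
# curate, populated with representative GO biological-process terms; a
# real analysis should replace the term lists with the ids that are
# significantly enriched in its own annotation release.
cardiovascular_disease:
  - GO:0007507    # heart development
  - GO:0072359    # circulatory system development
  - GO:0001944    # vasculature development
cell_apoptosis:
  - GO:0006915    # apoptotic process
  - GO:0043065    # positive regulation of apoptotic process
metabolism:
  - GO:0008152    # metabolic process
  - GO:0006006    # glucose metabolic process
inflammatory_immunity:
  - GO:0006954    # inflammatory response
  - GO:0006955    # immune response
chondroitin_sulfate:
  - GO:0030206    # chondroitin sulfate biosynthetic process
  - GO:0030204    # chondroitin sulfate metabolic process
cell_polarity:
  - GO:0007163    # establishment or maintenance of cell polarity
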