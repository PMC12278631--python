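# Default MDC (Mitochondrial Disease Criteria) configuration.
#
# Each entry scores one clinical feature: the entry matches when its HPO
# branch term appears in a proband's ancestor-expanded term set.  Domain
# subscores are capped, and the total score is capped at 12
# (unlikely 0-1, possible 2-4, probable 5-7, definite 8-12).
#
# The exact published weight table of the HPO adaptation is not
# reproduced here; this shipped default covers the same clinical domains
# and is an editable approximation.

domain_caps:
  muscular: 2
  neurological: 2
  multisystem: 3
  metabolic: 4
  imaging: 2
  histopathology: 4

entries:
  # muscular
  - {branch: "HP:0003198", domain: muscular, weight: 2}        # Myopathy
  - {branch: "HP:0001252", domain: muscular, weight: 1}        # Hypotonia
  - {branch: "HP:0003324", domain: muscular, weight: 1}        # Generalized muscle weakness
  - {branch: "HP:0003546", domain: muscular, weight: 1}        # Exercise intolerance
  # neurological
  - {branch: "HP:0001250", domain: neurological, weight: 1}    # Seizure
  - {branch: "HP:0002376", domain: neurological, weight: 2}    # Developmental regression
  - {branch: "HP:0012758", domain: neurological, weight: 1}    # Neurodevelopmental delay
  - {branch: "HP:0000505", domain: neurological, weight: 1}    # Visual impairment
  # multisystem
  - {branch: "HP:0000365", domain: multisystem, weight: 1}     # Hearing impairment
  - {branch: "HP:0001638", domain: multisystem, weight: 1}     # Cardiomyopathy
  - {branch: "HP:0001508", domain: multisystem, weight: 1}     # Failure to thrive
  - {branch: "HP:0000124", domain: multisystem, weight: 1}     # Renal tubular dysfunction
  - {branch: "HP:0001903", domain: multisystem, weight: 1}     # Anemia
  - {branch: "HP:0001875", domain: multisystem, weight: 1}     # Neutropenia
  # metabolic
  - {branch: "HP:0003128", domain: metabolic, weight: 2}       # Lactic acidosis
  - {branch: "HP:0002151", domain: metabolic, weight: 1}       # Increased serum lactate
  - {branch: "HP:0001987", domain: metabolic, weight: 1}       # Hyperammonemia
  # imaging
  - {branch: "HP:0002500", domain: imaging, weight: 1}         # Abnormal cerebral white matter morphology
  - {branch: "HP:0001272", domain: imaging, weight: 1}         # Cerebellar atrophy
  # histopathology
  - {branch: "HP:0003200", domain: histopathology, weight: 2}  # Ragged-red muscle fibers
  - {branch: "HP:0003688", domain: histopathology, weight: 2}  # Cytochrome C oxidase-negative fibers
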