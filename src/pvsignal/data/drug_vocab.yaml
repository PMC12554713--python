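# Editable synonym dictionary for the 12 study antiepileptic drugs.
# Canonical name -> list of synonyms (generic spellings, salts, brand names).
# This is a repository fixture seeded with common US brands, not a claim of
# any particular study's exact search strings. Matching is exact (after
# uppercasing and trailing dose/form-token stripping); see pvsignal.vocab.
CARBAMAZEPINE:
  - TEGRETOL
  - CARBATROL
  - EPITOL
  - EQUETRO
ETHOSUXIMIDE:
  - ZARONTIN
PHENYTOIN:
  - PHENYTOIN SODIUM
  - DILANTIN
  - PHENYTEK
VALPROIC ACID:
  - VALPROATE
  - VALPROATE SODIUM
  - SODIUM VALPROATE
  - DIVALPROEX SODIUM
  - DEPAKOTE
  - DEPAKENE
  - DEPACON
GABAPENTIN:
  - NEURONTIN
  - GRALISE
  - HORIZANT
  - GABAPENTIN ENACARBIL
LAMOTRIGINE:
  - LAMICTAL
LEVETIRACETAM:
  - KEPPRA
  - SPRITAM
OXCARBAZEPINE:
  - TRILEPTAL
  - OXTELLAR
TOPIRAMATE:
  - TOPAMAX
  - TROKENDI
  - QUDEXY
ZONISAMIDE:
  - ZONEGRAN
ESLICARBAZEPINE:
  - ESLICARBAZEPINE ACETATE
  - APTIOM
  - ZEBINIX
LACOSAMIDE:
  - VIMPAT
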