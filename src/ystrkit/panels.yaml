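# Built-in forensic Y-STR panel registry.
#
# Panels form a nested chain: each entry either lists its loci in full or
# extends a previously defined panel with additional loci.  Locus names follow
# the YHRD convention; the multi-copy marker DYS385a/b occupies one column and
# normally carries two allele values.
multi_copy:
  DYS385a/b: 2
panels:
  - name: Minimal
    loci:
      - DYS19
      - DYS389I
      - DYS389II
      - DYS390
      - DYS391
      - DYS392
      - DYS393
      - DYS385a/b
  - name: PowerPlexY12
    extends: Minimal
    add:
      - DYS437
      - DYS438
      - DYS439
  - name: Yfiler
    extends: PowerPlexY12
    add:
      - DYS448
      - DYS456
      - DYS458
      - DYS635
      - YGATAH4
  - name: PowerPlexY23
    extends: Yfiler
    add:
      - DYS481
      - DYS533
      - DYS549
      - DYS570
      - DYS576
      - DYS643
  - name: Microreader24Y
    extends: PowerPlexY23
    add:
      - DYS460
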