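# Replicating the published cluster counts on the real data

The bundled synthetic generator exercises every stage of the pipeline, but
the published cluster counts for the EHMT2-degron experiment (13 ECORDs at
24 h, 29 at 7 days of depletion in bulk mESCs; 91 in sorted 2-cell-like
cells and 7 in sorted mESCs) can only be reproduced from the real data,
which requires external downloads and upstream tooling that are deliberately
outside this package:

1. **Expression data.** RNA-seq counts from GEO accession **GSE280606**
   (bulk mESC time course and MERVL-reporter-sorted populations).  Align
   (e.g. STAR) and call differential expression with DESeq2 per contrast
   (dTAG vs DMSO at 24 h and 7 d; sorted 2CLC vs mESC).  Export a TSV per
   contrast with columns `gene_id`, `log2fc` (log2 fold change), `padj`
   (adjusted p, `NA` for genes removed by independent filtering).
2. **Gene annotation.** GENCODE vM25 gene records (mm10), GTF.
3. **TAD intervals.** mESC TAD calls (BED) from published Hi-C.
4. **Run the caller.**

   ```
   ecordkit call-ecords --genes gencode.vM25.gtf --degs deseq2_24h.tsv \
       --tads mesc_tads.bed --min-degs 4 --max-static 0.5 --out ecords_24h.bed
   ```

   Use `--min-degs 4` (bulk contrasts) or `--min-degs 5` (sorted-cell
   contrast), `alpha = 0.05`, `lfc = 1.0`, and the strict (`< 0.5`)
   static-fraction threshold.
5. **Shuffle null.** `ecordkit shuffle-curve` with `--n-deg` set to the
   contrast's DEG count and the expressed-gene universe from the DESeq2
   output reproduces the chance-clustering curves.

The resulting ECORD BED files can be compared across contrasts with
`ecord_overlap` (bulk vs sorted-cell calls overlap almost completely on the
real data).  None of these steps run in this repository's test suite; they
are a recipe for users with access to the raw data.
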