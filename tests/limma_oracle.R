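# Independent oracle: moderated two-group test via Bioconductor limma.
# Usage: Rscript limma_oracle.R <log2matrix.tsv> <groups.txt> <out.tsv>
suppressMessages(library(limma))
args <- commandArgs(trailingOnly = TRUE)
x <- as.matrix(read.table(args[1], sep = "\t", header = TRUE, row.names = 1))
groups <- strsplit(readLines(args[2])[1], "\t")[[1]]
design <- model.matrix(~0 + factor(groups, levels = unique(groups)))
colnames(design) <- c("g1", "g2")
fit <- lmFit(x, design)
fit <- contrasts.fit(fit, makeContrasts(g1 - g2, levels = design))
fit <- eBayes(fit)
out <- data.frame(
  logFC = fit$coefficients[, 1],
  t = fit$t[, 1],
  p = fit$p.value[, 1],
  d0 = fit$df.prior,
  s02 = fit$s2.prior
)
write.table(out, args[3], sep = "\t", quote = FALSE)
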