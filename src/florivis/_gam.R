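# Batch GAM fitting backend for florivis.trends (mgcv).
#
# Usage: Rscript _gam.R <input.csv> <summary.csv> <pred.csv> <family> <k> <n_pred> <method>
#   input.csv: series_id, day, y  (y already offset-adjusted for gamma models)
#   family:    gamma  -> Gamma(link = "log")
#              negbin -> nb() with theta estimated during fitting
#   method:    mgcv smoothing-parameter criterion ("GCV.Cp", "REML", ...)
#
# One model per series_id: y ~ s(day, k = k). Fit failures are reported in
# the summary's `error` column instead of aborting the batch.

suppressMessages(library(mgcv))

args <- commandArgs(trailingOnly = TRUE)
input_csv <- args[1]
summary_csv <- args[2]
pred_csv <- args[3]
family_name <- args[4]
k <- as.integer(args[5])
n_pred <- as.integer(args[6])
method <- args[7]

dat <- read.csv(input_csv, stringsAsFactors = FALSE)

summaries <- list()
preds <- list()

for (sid in unique(dat$series_id)) {
  d <- dat[dat$series_id == sid, ]
  res <- tryCatch({
    if (family_name == "gamma") {
      fam <- Gamma(link = "log")
    } else if (family_name == "negbin") {
      fam <- nb()
    } else {
      stop(sprintf("unknown family '%s'", family_name))
    }
    m <- gam(y ~ s(day, k = k), data = d, family = fam, method = method)
    s <- summary(m)
    theta <- if (family_name == "negbin") m$family$getTheta(TRUE) else NA_real_
    grid <- seq(min(d$day), max(d$day), length.out = n_pred)
    mu <- as.numeric(predict(m, newdata = data.frame(day = grid),
                             type = "response"))
    list(
      summary = data.frame(
        series_id = sid,
        n_obs = nrow(d),
        intercept = s$p.table[1, 1],
        intercept_se = s$p.table[1, 2],
        intercept_stat = s$p.table[1, 3],
        intercept_p = s$p.table[1, 4],
        edf = s$s.table[1, 1],
        ref_df = s$s.table[1, 2],
        statistic = s$s.table[1, 3],
        p_value = s$s.table[1, 4],
        dev_expl_pct = 100 * s$dev.expl,
        theta = theta,
        error = "",
        stringsAsFactors = FALSE
      ),
      pred = data.frame(series_id = sid, day = grid, prediction = mu)
    )
  }, error = function(e) {
    list(
      summary = data.frame(
        series_id = sid, n_obs = nrow(d),
        intercept = NA_real_, intercept_se = NA_real_,
        intercept_stat = NA_real_, intercept_p = NA_real_,
        edf = NA_real_, ref_df = NA_real_, statistic = NA_real_,
        p_value = NA_real_, dev_expl_pct = NA_real_, theta = NA_real_,
        error = conditionMessage(e), stringsAsFactors = FALSE
      ),
      pred = NULL
    )
  })
  summaries[[length(summaries) + 1]] <- res$summary
  if (!is.null(res$pred)) preds[[length(preds) + 1]] <- res$pred
}

write.csv(do.call(rbind, summaries), summary_csv, row.names = FALSE)
if (length(preds) > 0) {
  write.csv(do.call(rbind, preds), pred_csv, row.names = FALSE)
} else {
  write.csv(data.frame(series_id = character(), day = numeric(),
                       prediction = numeric()), pred_csv, row.names = FALSE)
}
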