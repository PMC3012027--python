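== category SG1 ==
constraint:                                     9                       !                                                     !          
SG1_000          YVSFHQATSTHGGKMKYSPDFEPAAELWPMLWAERFIATGGVMTPRCMMCINCIITTIYNPPQEKFQCYFQHVQFTPWNDEWNSVPNIKTAVLMCSAHYDYQKNVHNIITSWEWQMTNKM
SG1_001          ACKSTWDWTTMWAAIWFENDNEQAHNMTQSEWATMVCHHDPSHVSDSVEDPPCQHSTHRVVEAQFNQIGLQDIDQTSINFFHLASNGCSWDDCWSHTAIKVIRTRSTVITMSEGMMVCEY
SG1_002          EYVWFCFDAMDEVLDPGMGDPMISVTDDYSFWFMYWAHNEFLVSTSRTQVHESEKTHWEMCYNTGTQPYKKQTHLFMSNRAYLARMRCNKWALPMCNSPVELSHNTLLTTPKNIMHLGMF
pattern:         ...............................W.......................S.....................................................T..........
wt_res_freqs:    ...............................9.......................9.....................................................9..........
bg|pattern:      ...............................W.......................S.....................................................T..........
bg|wt_res_freqs: ...............................0.......................1.....................................................0..........
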