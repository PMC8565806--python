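drug,n_serious,n_total
Ceftezole,168,2325
Ceftazidime,126,1692
Cefamandole nafate,73,1589
Cefoperazone/Sulbactam,143,1565
Cefuroxime,77,1394
Cefotaxime,104,1328
Ceftriaxone,82,1128
Cefoperazone/Tazobactam,60,924
Cefathiamidine,44,815
Ceftizoxime,35,700
Ceftriaxone/Tazobactam,33,425
Cefotaxime/Sulbactam,27,314
Cefixime,12,253
Cefazolin pentahydrate,13,240
Cefotiam,9,231
Cefazolin,16,169
Cefaclor,7,150
Cefmenoxime,1,97
Cefodizime,6,93
Cefazedone,2,65
Cefepime,2,64
Cefoperazone,4,56
Cefpiramide,0,56
Cefdinir,2,55
Cefadroxil,2,37
Cefprozil,0,23
Cefalexin,0,17
Cefradine,1,16
Cefuroxime axetil,1,14
Cefpodoxime proxetil,0,6
Ceftazidime/Tazobactam,1,4
Cefonicid,0,3
Cefalotin,0,2
Cefalexin/Trimethoprim,0,1
Ceftriaxone/Sulbactam,0,1
Cefoselis,0,1
Ceftizoxime/Sulbactam,0,1
Unknown,1,3
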