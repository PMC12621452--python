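group,metric,mean,sd,n,sem_published
crustacean,NRF6.2,123.76,33.83,152,2.74
crustacean,NRF9.2,167.19,27.27,152,2.21
cichlid,NRF6.2,75.52,37.0,24,7.55
cichlid,NRF9.2,219.19,17.2,24,3.51
cod,NRF6.2,69.33,21.1,48,3.05
cod,NRF9.2,153.33,14.6,48,2.10
demersal,NRF6.2,89.55,39.9,96,4.07
demersal,NRF9.2,120.27,39.9,96,4.07
small_pelagic,NRF6.2,103.0,2.85,12,0.82
small_pelagic,NRF9.2,288.80,9.39,12,2.71
salmonid,NRF6.2,90.53,15.3,69,1.85
salmonid,NRF9.2,151.69,28.6,69,3.45
bivalve,NRF6.2,192.46,,66,6.16
bivalve,NRF9.2,229.38,,66,5.61
gastropod,NRF6.2,84.80,,12,4.66
gastropod,NRF9.2,149.97,,12,8.02
cephalopod,NRF6.2,131.74,,36,4.03
cephalopod,NRF9.2,207.45,,36,2.53
crustacean,protein,20.1,3.09,152,
cichlid,protein,20.9,2.25,24,
cod,protein,21.6,2.58,48,
demersal,protein,20.7,2.91,96,
small_pelagic,protein,23.8,3.51,12,
salmonid,protein,22.5,2.03,69,
bivalve,protein,19.5,10.0,66,
gastropod,protein,19.5,10.0,12,
cephalopod,protein,19.5,10.0,36,
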