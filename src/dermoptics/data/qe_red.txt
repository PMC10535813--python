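# idealized camera quantum efficiency, red channel
# Gaussian response centered at 630 nm (sigma 35 nm), relative units
# columns: wavelength_nm  relative_response
450 1.80583e-06
455 3.72665e-06
460 7.53525e-06
465 1.49284e-05
470 2.89778e-05
475 5.51131e-05
480 0.000102703
485 0.000187519
490 0.000335463
495 0.000588005
500 0.00100984
505 0.00169928
510 0.00280164
515 0.00452581
520 0.00716336
525 0.011109
530 0.0168799
535 0.0251305
540 0.036658
545 0.0523931
550 0.0733697
555 0.100669
560 0.135335
565 0.178264
570 0.230066
575 0.290924
580 0.360448
585 0.437565
590 0.52045
595 0.606531
600 0.692569
605 0.774837
610 0.849366
615 0.912254
620 0.960005
625 0.989848
630 1
635 0.989848
640 0.960005
645 0.912254
650 0.849366
655 0.774837
660 0.692569
665 0.606531
670 0.52045
675 0.437565
680 0.360448
685 0.290924
690 0.230066
695 0.178264
700 0.135335
705 0.100669
710 0.0733697
715 0.0523931
720 0.036658
725 0.0251305
730 0.0168799
735 0.011109
740 0.00716336
745 0.00452581
750 0.00280164
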